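import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from methylpop import differential_methylation as dm
from conftest import make_matrix


class TestVariabilityFilter:
    def test_constant_site_removed(self):
        res = dm.variability_filter(np.zeros((1, 8)))
        assert not res.retained[0]

    def test_sample_sd_formula(self):
        pct = np.array([[0, 0, 0, 0, 0, 0, 0, 40.0]])
        res = dm.variability_filter(pct)
        assert res.sd[0] == pytest.approx(14.142, abs=1e-3)
        assert res.retained[0]

    def test_strict_inequality_at_boundary(self):
        # SD exactly 2 is removed (SD > 2 is strict)
        pct = np.array([[0.0, 4.0]])  # sd = 2.828
        assert dm.variability_filter(pct).retained[0]
        pct = np.array([[1.0, 1.0, 1.0, 1.0]])
        assert not dm.variability_filter(pct).retained[0]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            dm.variability_filter(np.zeros((3, 1)))

    def test_excluded_percentage_accounting(self):
        rng = np.random.default_rng(0)
        pct = rng.uniform(0, 100, (500, 8))
        res = dm.variability_filter(pct)
        assert res.n_input == res.n_retained + round(
            res.pct_excluded / 100 * res.n_input)


class TestDmTest:
    def test_hand_computed_2x2(self):
        # pooled 30/100 vs 10/100, samples exactly at group proportions
        cov = np.array([[50, 50, 50, 50]])
        meth = np.array([[15, 15, 5, 5]])
        m = make_matrix(cov, meth, ["CA", "CA", "OR", "OR"])
        res = dm.dm_test(m, "CA", "OR")
        assert res["statistic"].iloc[0] == pytest.approx(12.5)
        assert res["meth_diff"].iloc[0] == pytest.approx(-20.0)

    def test_identical_groups_null(self):
        m = make_matrix([[20, 20]], [[5, 5]], ["CA", "OR"])
        res = dm.dm_test(m, "CA", "OR")
        assert res["statistic"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_both_groups_fixed_p_is_one(self):
        m = make_matrix([[20, 20]], [[0, 0]], ["CA", "OR"])
        assert dm.dm_test(m, "CA", "OR")["p"].iloc[0] == 1.0
        m = make_matrix([[20, 20]], [[20, 20]], ["CA", "OR"])
        assert dm.dm_test(m, "CA", "OR")["p"].iloc[0] == 1.0

    def test_zero_coverage_group_flagged(self):
        m = make_matrix([[0, 20]], [[0, 5]], ["CA", "OR"])
        res = dm.dm_test(m, "CA", "OR")
        assert bool(res["skipped"].iloc[0]) and np.isnan(res["p"].iloc[0])

    def test_matches_textbook_chi2_when_no_overdispersion(self):
        # one sample per group: phi cannot be estimated, plain Pearson X2
        from scipy.stats import chi2_contingency
        rng = np.random.default_rng(5)
        for _ in range(25):
            cov = rng.integers(20, 80, (1, 2))
            meth = rng.integers(5, 15, (1, 2))
            m = make_matrix(cov, meth, ["CA", "OR"])
            res = dm.dm_test(m, "CA", "OR")
            table = np.array([[meth[0, 0], cov[0, 0] - meth[0, 0]],
                              [meth[0, 1], cov[0, 1] - meth[0, 1]]])
            expected = chi2_contingency(table, correction=False)[0]
            assert res["statistic"].iloc[0] == pytest.approx(expected)

    def test_overdispersed_counts_raise_phi_and_calibrate(self):
        rng = np.random.default_rng(11)
        n, rho = 4000, 0.2
        level = rng.beta(2, 2, n)
        cov = rng.negative_binomial(10, 10 / 85, (n, 8))
        lam = (1 - rho) / rho
        p_site = rng.beta(level[:, None] * lam, (1 - level[:, None]) * lam,
                          (n, 8))
        meth = rng.binomial(cov, p_site)
        m = make_matrix(cov, meth, ["CA"] * 4 + ["OR"] * 4)
        res = dm.dm_test(m, "CA", "OR")
        assert res["phi"].mean() > 1
        corrected_rate = (res["p"] < 0.05).mean()
        raw = res["statistic"] * np.maximum(1.0, res["phi"])
        from scipy.stats import chi2
        raw_rate = (chi2.sf(raw, 1) < 0.05).mean()
        assert abs(corrected_rate - 0.05) < abs(raw_rate - 0.05)


class TestBhFdr:
    def test_step_up_by_hand(self):
        q = dm.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_and_unit_pvalues(self):
        assert dm.bh_fdr(np.array([0.3]))[0] == pytest.approx(0.3)
        assert dm.bh_fdr(np.array([1.0, 0.5]))[0] == 1.0

    def test_nan_propagates(self):
        q = dm.bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and np.isfinite(q[0])

    def test_matches_brute_force_definition(self):
        # q_i = min over {j : p_(j) >= p_i} of p_(j) * m / j
        rng = np.random.default_rng(2)
        for _ in range(30):
            p = rng.uniform(0, 1, rng.integers(1, 21))
            m = p.size
            order = np.sort(p)
            brute = np.empty_like(p)
            for i, pi in enumerate(p):
                cand = [order[j] * m / (j + 1) for j in range(m)
                        if order[j] >= pi]
                brute[i] = min(1.0, min(cand))
            assert np.allclose(dm.bh_fdr(p), brute, atol=1e-12)


class TestCalls:
    def _frame(self, q, diff):
        return pd.DataFrame({"pct_pop1": [50.0], "pct_pop2": [50.0 + diff],
                             "meth_diff": [diff], "statistic": [1.0],
                             "phi": [1.0], "p": [q], "q": [q],
                             "skipped": [False]})

    def test_significant_hyper_in_focal(self):
        out = dm.call_dm_sites(self._frame(0.005, 12.0), focal_pop="OR",
                               pop1="CA", pop2="OR")
        assert out["direction"].iloc[0] == "hyper"

    def test_diff_below_threshold_not_significant(self):
        out = dm.call_dm_sites(self._frame(0.005, 9.9), focal_pop="OR",
                               pop1="CA", pop2="OR")
        assert not out["significant"].iloc[0]
        assert out["direction"].iloc[0] == "none"

    def test_focal_population_flips_direction(self):
        out = dm.call_dm_sites(self._frame(0.005, -15.0), focal_pop="OR",
                               pop1="CA", pop2="OR")
        assert out["direction"].iloc[0] == "hypo"
        out = dm.call_dm_sites(self._frame(0.005, -15.0), focal_pop="CA",
                               pop1="CA", pop2="OR")
        assert out["direction"].iloc[0] == "hyper"

    def test_unknown_focal_rejected(self):
        with pytest.raises(ValueError):
            dm.call_dm_sites(self._frame(0.5, 0.0), focal_pop="XX",
                             pop1="CA", pop2="OR")

    def test_hypo_plus_hyper_equals_total(self):
        rng = np.random.default_rng(9)
        n = 400
        frame = pd.DataFrame({
            "pct_pop1": rng.uniform(0, 100, n),
            "meth_diff": rng.uniform(-40, 40, n),
            "p": rng.uniform(0, 0.2, n), "skipped": False,
        })
        frame["pct_pop2"] = frame["pct_pop1"] + frame["meth_diff"]
        frame["q"] = dm.bh_fdr(frame["p"].to_numpy())
        out = dm.call_dm_sites(frame, focal_pop="OR", pop1="CA", pop2="OR")
        s = dm.dm_summary(out)
        assert s["n_hypo"] + s["n_hyper"] == s["n_significant"]


class TestStructureViews:
    def test_identical_samples_zero_variance(self):
        pct = np.tile(np.array([[10.0], [20.0], [30.0]]), (1, 3))
        coords, var = dm.pca_samples(pct)
        assert np.allclose(var, 0) and np.allclose(coords, 0)

    def test_single_differing_site_pc1_explains_all(self):
        pct = np.array([[10.0, 30.0], [5.0, 5.0]])
        _, var = dm.pca_samples(pct)
        assert var[0] == pytest.approx(1.0)

    def test_cluster_identical_samples_merge_at_zero(self):
        pct = np.array([[0.0, 0.0, 50.0], [10.0, 10.0, 60.0],
                        [20.0, 20.0, 0.0]])
        link = dm.cluster_samples(pct)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-10)

    def test_cluster_anticorrelated_pairs(self):
        up = np.array([0.0, 10, 20, 30])
        down = up[::-1]
        pct = np.column_stack([up, up + 1, down, down + 1])
        link = dm.cluster_samples(pct)
        labels = fcluster(link, 2, criterion="maxclust")
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_zero_variance_profile_names_sample(self):
        pct = np.array([[1.0, 5.0], [1.0, 6.0]])
        with pytest.raises(ValueError, match="flatty"):
            dm.cluster_samples(pct, sample_ids=["flatty", "ok"])

    def test_populations_separate_on_fixture(self, sim_default, char_default):
        from methylpop import pipeline as pl
        res = pl.run_diffmeth(char_default["matrix"], "CA", "OR",
                              pl.PipelineConfig())
        pops = np.asarray(char_default["matrix"].populations)
        pc1 = res["pca_coords"][:, 0]
        assert (pc1[pops == "CA"].mean() < pc1[pops == "OR"].mean()) or \
               (pc1[pops == "CA"].mean() > pc1[pops == "OR"].mean())
        # silhouette of PC1 labelling is positive
        ca, orr = pc1[pops == "CA"], pc1[pops == "OR"]
        between = abs(ca.mean() - orr.mean())
        within = max(ca.std(), orr.std())
        assert between > within
        labels = fcluster(res["linkage"], 2, criterion="maxclust")
        assert len(set(labels[pops == "CA"])) == 1
        assert len(set(labels[pops == "OR"])) == 1
        assert labels[pops == "CA"][0] != labels[pops == "OR"][0]


class TestScaffoldDensity:
    def test_uniform_density_correlates_with_length(self):
        lengths = {f"s{i}": 1000 * (i + 1) for i in range(8)}
        rows = []
        for s, L in lengths.items():
            rows += [{"scaffold": s, "position": p}
                     for p in range(1, L, 100)]  # ~L/100 sites each
        table, summary = dm.scaffold_dm_density(pd.DataFrame(rows), lengths)
        assert summary["pearson_r"] > 0.99

    def test_no_dm_sites_correlation_omitted(self):
        table, summary = dm.scaffold_dm_density(
            pd.DataFrame(columns=["scaffold", "position"]),
            {"a": 100, "b": 200, "c": 300})
        assert summary is None and (table["n_dm"] == 0).all()

    def test_fewer_than_three_scaffolds_counts_only(self):
        df = pd.DataFrame({"scaffold": ["a"], "position": [1]})
        table, summary = dm.scaffold_dm_density(df, {"a": 100, "b": 200})
        assert summary is None and table.set_index("scaffold").n_dm["a"] == 1
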