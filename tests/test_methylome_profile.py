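import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylpop import methylome_profile as mp
from methylpop.meth_io import GeneModel, Transcript
from conftest import make_matrix


def _gene(gene_id, scaffold, strand, exons, cds=None):
    start = min(s for s, _ in exons)
    end = max(e for _, e in exons)
    tx = Transcript(tx_id=f"{gene_id}.t1", exons=sorted(exons),
                    cds=sorted(cds) if cds else [])
    return GeneModel(gene_id, scaffold, strand, start, end, [tx])


class TestClassification:
    @pytest.mark.parametrize("mean,expected", [
        (5.0, "unmethylated"), (25.0, "sparse"), (60.0, "high"),
        (50.0, "high"), (10.0, "sparse"), (0.0, "unmethylated"),
    ])
    def test_three_class_boundaries(self, mean, expected):
        assert mp.classify_sites(np.array([mean]))[0] == expected

    def test_bad_boundaries_rejected(self):
        with pytest.raises(ValueError):
            mp.classify_sites(np.array([1.0]), low=50, high=10)

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(0)
        means = rng.uniform(0, 100, 5000)
        classes = mp.classify_sites(means)
        counts = pd.Series(classes).value_counts()
        assert counts.sum() == 5000


def test_percent_methylation_and_mean():
    m = make_matrix([[20, 10]], [[5, 0]], ["A", "B"])
    pct, mean = mp.percent_methylation(m)
    assert pct[0, 0] == 25.0 and pct[0, 1] == 0.0
    assert mean[0] == 12.5


def test_sample_summary_means_and_population_sd():
    m = make_matrix([[10, 10], [10, 10]], [[0, 0], [5, 5]], ["A", "A"])
    s = mp.sample_summary(m)
    samp = s[s.level == "sample"]
    assert (samp.mean_pct == 25.0).all()  # sites at 0% and 50%
    pop = s[s.level == "population"].iloc[0]
    assert pop.mean_pct == 25.0 and pop.sd_pct == 0.0


class TestFeatureTrack:
    def test_single_gene_interval_arithmetic(self):
        g = _gene("g1", "s1", "+", [(1001, 2000)], cds=[(1001, 2000)])
        track = mp.build_feature_track([g], scaffold_lengths={"s1": 10_000},
                                       flank=1000)
        sites = pd.DataFrame({"scaffold": "s1",
                              "position": [500, 1500, 2500, 5000],
                              "strand": "F"})
        labels = mp.annotate_sites(sites, track)
        assert list(labels) == ["upstream_flank", "CDS", "downstream_flank",
                                "intergenic"]

    def test_no_genes_everything_intergenic(self):
        track = mp.build_feature_track([], scaffold_lengths={"s1": 1000})
        sites = pd.DataFrame({"scaffold": "s1", "position": [1, 500, 1000],
                              "strand": "F"})
        assert set(mp.annotate_sites(sites, track)) == {"intergenic"}

    def test_precedence_cds_beats_te(self):
        g = _gene("g1", "s1", "+", [(100, 200)], cds=[(100, 200)])
        track = mp.build_feature_track([g], te_intervals=[("s1", 50, 300)],
                                       scaffold_lengths={"s1": 1000})
        sites = pd.DataFrame({"scaffold": "s1", "position": [150, 250],
                              "strand": "F"})
        assert list(mp.annotate_sites(sites, track)) == ["CDS", "TE"]

    def test_site_off_scaffold_raises(self):
        track = mp.build_feature_track([], scaffold_lengths={"s1": 100})
        sites = pd.DataFrame({"scaffold": "s1", "position": [101], "strand": "F"})
        with pytest.raises(ValueError):
            mp.annotate_sites(sites, track)

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            mp.build_feature_track([], flank=-1)

    def test_annotation_total_and_single_valued_on_random_tracks(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            genes = []
            pos = 1
            for i in range(rng.integers(0, 4)):
                s = pos + int(rng.integers(50, 500))
                e = s + int(rng.integers(50, 400))
                genes.append(_gene(f"g{i}", "s1", rng.choice(["+", "-"]),
                                   [(s, e)], cds=[(s, e)]))
                pos = e + 1
            track = mp.build_feature_track(genes, scaffold_lengths={"s1": 5000},
                                           flank=int(rng.integers(0, 200)))
            sites = pd.DataFrame({"scaffold": "s1",
                                  "position": rng.integers(1, 5001, 100),
                                  "strand": "F"})
            labels = mp.annotate_sites(sites, track)
            assert len(labels) == 100
            assert set(labels) <= set(mp.FEATURE_PRECEDENCE)


def test_feature_breakdown_percentages():
    classes = np.array(["high", "high", "unmethylated"])
    feats = np.array(["CDS", "intron", "intron"])
    bd = mp.feature_breakdown(classes, feats)
    high = bd[bd["class"] == "high"].set_index("feature")
    assert high.loc["CDS", "pct_of_class"] == 50.0
    assert high.loc["intron", "pct_of_class"] == 50.0
    # relative rate: 1 high of 2 intron CpGs
    assert high.loc["intron", "relative_pct"] == 50.0
    # percentages sum to 100 within each class with sites
    for cls in ("high", "unmethylated", "all"):
        sub = bd[bd["class"] == cls]
        assert sub["pct_of_class"].sum() == pytest.approx(100.0, abs=0.05)


def test_feature_breakdown_relative_rate_example():
    # 9 high of 96 CpGs in a feature -> 9.375%
    classes = np.array(["high"] * 9 + ["unmethylated"] * 87)
    feats = np.array(["CDS"] * 96)
    bd = mp.feature_breakdown(classes, feats)
    row = bd[(bd["class"] == "high") & (bd.feature == "CDS")].iloc[0]
    assert row.relative_pct == pytest.approx(9.375)


def test_empty_class_has_zero_row_no_division_error():
    bd = mp.feature_breakdown(np.array(["unmethylated"]), np.array(["CDS"]))
    assert (bd[bd["class"] == "sparse"]["count"] == 0).all()


class TestChisqEnrichment:
    def test_yates_hand_computed_example(self):
        stat, p = mp.yates_chi2_2x2([[10, 90], [50, 50]])
        assert stat == pytest.approx(36.214, abs=1e-3)

    def test_identical_proportions_give_zero(self):
        stat, p = mp.yates_chi2_2x2([[30, 70], [30, 70]])
        assert stat == 0.0 and p == 1.0

    def test_bh_equal_pvalues_unchanged(self):
        from methylpop.differential_methylation import bh_fdr
        q = bh_fdr(np.full(8, 0.01))
        assert np.allclose(q, 0.01)

    def test_enrichment_table_shape(self):
        rng = np.random.default_rng(1)
        feats = rng.choice(mp.FEATURE_PRECEDENCE, 2000)
        classes = np.where(rng.random(2000) < 0.1, "high", "unmethylated")
        df = mp.chisq_feature_enrichment(classes, feats)
        assert len(df) == len(mp.FEATURE_PRECEDENCE)
        ok = df["p"].notna()
        assert (df.loc[ok, "q"] >= df.loc[ok, "p"] - 1e-12).all()


class TestLongestIsoform:
    def test_longest_by_exon_sum(self):
        g = GeneModel("g", "s1", "+", 1, 3000, [
            Transcript("t_short", exons=[(1, 900)]),
            Transcript("t_long", exons=[(1, 600), (1000, 1599)]),
        ])
        assert mp.longest_isoform([g])["g"].tx_id == "t_long"

    def test_tie_broken_by_smaller_id(self):
        g = GeneModel("g", "s1", "+", 1, 2000, [
            Transcript("t_b", exons=[(1, 1000)]),
            Transcript("t_a", exons=[(1001, 2000)]),
        ])
        assert mp.longest_isoform([g])["g"].tx_id == "t_a"

    def test_single_isoform_unchanged(self):
        g = _gene("g", "s1", "+", [(1, 100)])
        assert mp.longest_isoform([g])["g"].tx_id == "g.t1"


class TestRankBreakdown:
    def test_minus_strand_rank_one_is_rightmost_exon(self):
        exons = [(100, 199), (300, 399), (500, 599)]  # E_a, E_b, E_c
        g = _gene("g", "s1", "-", exons)
        sites = pd.DataFrame({"scaffold": "s1", "position": [550, 150, 350],
                              "strand": "F"})
        classes = np.array(["high", "high", "unmethylated"])
        prof = mp.exon_intron_rank_breakdown(sites, classes, [g])
        high = prof[(prof["class"] == "high") & (prof.kind == "exon")]
        got = dict(zip(high["rank"], high["count"]))
        assert got[1] == 1  # E_c (rightmost) is rank 1 on minus strand
        assert got[3] == 1  # E_a is rank 3

    def test_all_unmethylated_zero_high_counts(self):
        g = _gene("g", "s1", "+", [(1, 100), (201, 300)])
        sites = pd.DataFrame({"scaffold": "s1", "position": [50, 250],
                              "strand": "F"})
        prof = mp.exon_intron_rank_breakdown(
            sites, np.array(["unmethylated"] * 2), [g])
        assert (prof[prof["class"] == "high"]["count"] == 0).all()

    def test_fixture_rank_profile_recovers_truth_shape(self, sim_default,
                                                       char_default):
        cfg = sim_default["cfg"]
        prof = char_default["ranks"]
        ex = prof[(prof.kind == "exon") & (prof["class"] == "high")
                  & (prof["rank"] <= len(cfg.w_high_exon_rank))]
        w = np.asarray(cfg.w_high_exon_rank)
        rho = stats.spearmanr(ex["relative_pct"],
                              w[ex["rank"].to_numpy() - 1]).statistic
        assert rho > 0.8
        # exon ranks 2-4 carry more methylation than exon 1
        rel = dict(zip(ex["rank"], ex["relative_pct"]))
        assert min(rel[2], rel[3], rel[4]) > rel[1]


class TestTssDistances:
    def test_plus_strand_sign_convention(self):
        g = _gene("g", "s1", "+", [(1000, 2000)])
        sites = pd.DataFrame({"scaffold": "s1", "position": [1500, 800, 1000],
                              "strand": "F"})
        d = mp.tss_distances(sites, [g])["distance"].to_numpy()
        assert list(d) == [500, -200, 0]

    def test_minus_strand_flips_sign(self):
        g = _gene("g", "s1", "-", [(3000, 5000)])
        sites = pd.DataFrame({"scaffold": "s1", "position": [4000], "strand": "F"})
        assert mp.tss_distances(sites, [g])["distance"].iloc[0] == 1000

    def test_tie_resolves_to_lower_coordinate_and_flags(self):
        g1 = _gene("g1", "s1", "+", [(100, 150)])
        g2 = _gene("g2", "s1", "+", [(300, 350)])
        sites = pd.DataFrame({"scaffold": "s1", "position": [200], "strand": "F"})
        out = mp.tss_distances(sites, [g1, g2])
        assert out["distance"].iloc[0] == 100  # downstream of g1 at 100
        assert bool(out["tie"].iloc[0])

    def test_summary_ratio_counts_zero_as_downstream(self):
        d = np.array([0.0, 5.0, 10.0, -3.0])
        s = mp.tss_summary(d)
        assert s["n_downstream"] == 3 and s["n_upstream"] == 1
        assert s["downstream_upstream_ratio"] == 3.0
        assert s["mean_abs_distance"] == pytest.approx(4.5)


class TestKsTwoSample:
    def test_disjoint_supports(self):
        D, _ = mp.ks_two_sample([1, 2, 3], [4, 5, 6])
        assert D == 1.0

    def test_identical_samples(self):
        D, p = mp.ks_two_sample([1, 2, 3], [1, 2, 3])
        assert D == 0.0 and p == 1.0

    def test_ecdf_enumeration_example(self):
        D, _ = mp.ks_two_sample([1, 2], [1, 3])
        assert D == pytest.approx(0.5)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mp.ks_two_sample([], [1.0])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 50)
        d1, _ = mp.ks_two_sample(x, y)
        d2, _ = mp.ks_two_sample(np.exp(x), np.exp(y))
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0
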