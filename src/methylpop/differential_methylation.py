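"""Population differential-methylation testing.

Sites are first screened for variability (sample SD of %methylation must
exceed a floor; invariant sites carry no information for a two-group
contrast).  Each retained CpG is then tested by pooling methylated /
unmethylated read counts per population into a 2x2 table and computing a
Pearson chi-square (df=1, no continuity correction), deflated by a basic
overdispersion correction: phi is estimated from per-sample Pearson
residuals against the pooled group proportions,

    phi = sum_s r_s^2 / (S - 2),   r_s = (m_s - c_s p_g) / sqrt(c_s p_g (1 - p_g)),

and the statistic is divided by max(1, phi) — the standard quasi-likelihood
scale treatment.  BH-adjusted q-values, a minimum percent-methylation
difference, and a named focal population yield hypo/hyper calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .site_filtering import UnitedMatrix


@dataclass
class VariabilityFilterResult:
    sd: np.ndarray
    retained: np.ndarray  # boolean
    sd_min: float

    @property
    def n_input(self) -> int:
        return int(self.sd.size)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def pct_excluded(self) -> float:
        return 100.0 * (self.n_input - self.n_retained) / self.n_input if self.n_input else 0.0


def variability_filter(percent_matrix: np.ndarray, sd_min: float = 2.0) -> VariabilityFilterResult:
    """Retain sites whose across-sample SD of %methylation exceeds ``sd_min``.

    SD uses the n-1 sample formula; the inequality is strict (SD > sd_min).
    """
    percent_matrix = np.asarray(percent_matrix, float)
    if percent_matrix.ndim != 2 or percent_matrix.shape[1] < 2:
        raise ValueError("need a dense sites x samples matrix with >= 2 samples")
    sd = percent_matrix.std(axis=1, ddof=1)
    return VariabilityFilterResult(sd=sd, retained=sd > sd_min, sd_min=sd_min)


def dm_test(matrix: UnitedMatrix, pop1: str, pop2: str) -> pd.DataFrame:
    """Per-site overdispersion-corrected chi-square between two populations.

    Returns a DataFrame aligned with ``matrix.sites``: pooled %methylation per
    population, meth_diff (pop2 - pop1, percentage points), the corrected
    statistic, phi, and the upper-tail chi-square p (df=1).  Sites where a
    group has zero total coverage are flagged ``skipped`` with NaN p; sites
    with pooled proportion 0 or 1 in both groups get p = 1 by convention.
    """
    idx = matrix.population_index()
    if pop1 not in idx or pop2 not in idx:
        raise ValueError(f"unknown population: {pop1!r} or {pop2!r}")
    i1, i2 = idx[pop1], idx[pop2]
    m1 = matrix.meth[:, i1].sum(axis=1).astype(float)
    c1 = matrix.coverage[:, i1].sum(axis=1).astype(float)
    m2 = matrix.meth[:, i2].sum(axis=1).astype(float)
    c2 = matrix.coverage[:, i2].sum(axis=1).astype(float)
    skipped = (c1 == 0) | (c2 == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(c1 > 0, m1 / c1, np.nan)
        p2 = np.where(c2 > 0, m2 / c2, np.nan)
    # 2x2 Pearson chi-square, df = 1
    a, b, c, d = m1, c1 - m1, m2, c2 - m2
    n = c1 + c2
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        x2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    # overdispersion from per-sample Pearson residuals vs pooled group proportions;
    # the scale is applied only where dispersion is significantly > 1 (chi-square
    # screen on the residual sum), so a binomial null keeps its nominal level
    S = matrix.n_samples
    phi = np.ones(matrix.n_sites)
    apply_phi = np.zeros(matrix.n_sites, dtype=bool)
    if S > 2:
        rss = np.zeros(matrix.n_sites)
        for cols, pg in ((i1, p1), (i2, p2)):
            cov = matrix.coverage[:, cols].astype(float)
            meth = matrix.meth[:, cols].astype(float)
            var = cov * (pg * (1.0 - pg))[:, None]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(var > 0, (meth - cov * pg[:, None]) / np.sqrt(var), 0.0)
            rss += (r ** 2).sum(axis=1)
        phi = rss / (S - 2)
        apply_phi = (phi > 1.0) & (stats.chi2.sf(rss, S - 2) < 0.05)
    stat = np.where(apply_phi, x2 / np.maximum(1.0, phi), x2)
    p = stats.chi2.sf(stat, df=1)
    both_fixed = ((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1))
    p = np.where(both_fixed, 1.0, p)
    p = np.where(skipped, np.nan, p)
    return pd.DataFrame({
        "pct_pop1": 100.0 * p1, "pct_pop2": 100.0 * p2,
        "meth_diff": 100.0 * (p2 - p1),
        "statistic": stat, "phi": phi, "p": p, "skipped": skipped,
    })


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p propagates to NaN q."""
    p = np.asarray(pvalues, float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_dm_sites(results: pd.DataFrame, focal_pop: str, pop1: str, pop2: str,
                  q_max: float = 0.01, diff_min: float = 10.0) -> pd.DataFrame:
    """Significance and direction calls on dm_test + bh_fdr output.

    A site is significant iff q <= q_max and |meth_diff| >= diff_min.  The
    direction is relative to the *focal* population: "hypo" if its pooled
    %methylation is the lower one, "hyper" if higher.
    """
    if focal_pop not in (pop1, pop2):
        raise ValueError(f"focal population {focal_pop!r} is neither {pop1!r} nor {pop2!r}")
    out = results.copy()
    if "q" not in out.columns:
        out["q"] = bh_fdr(out["p"].to_numpy())
    sig = (out["q"].to_numpy() <= q_max) & \
          (np.abs(out["meth_diff"].to_numpy()) >= diff_min)
    sig &= ~out["skipped"].to_numpy() if "skipped" in out.columns else True
    focal_minus_other = out["meth_diff"].to_numpy() * (1.0 if focal_pop == pop2 else -1.0)
    direction = np.full(len(out), "none", dtype=object)
    direction[sig & (focal_minus_other < 0)] = "hypo"
    direction[sig & (focal_minus_other > 0)] = "hyper"
    out["significant"] = sig
    out["direction"] = direction
    return out


def dm_summary(calls: pd.DataFrame) -> dict:
    n_hypo = int((calls["direction"] == "hypo").sum())
    n_hyper = int((calls["direction"] == "hyper").sum())
    n = int(calls["significant"].sum())
    return {"n_significant": n, "n_hypo": n_hypo, "n_hyper": n_hyper,
            "hypo_pct": 100.0 * n_hypo / n if n else np.nan}


def pca_samples(percent_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA of samples on the site x sample %methylation matrix.

    Sites are centered; returns (coordinates: samples x PCs, variance
    fractions).  A constant matrix yields all-zero coordinates and variance.
    """
    X = np.asarray(percent_matrix, float).T  # samples x sites
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        k = min(X.shape)
        return np.zeros((X.shape[0], k)), np.zeros(k)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    coords = U * s
    var = s ** 2
    return coords, var / var.sum()


def cluster_samples(percent_matrix: np.ndarray, sample_ids: list[str] | None = None):
    """Ward.D2 hierarchical clustering on 1 - Pearson correlation distances.

    Returns the scipy linkage matrix.  A zero-variance sample profile makes
    the correlation undefined and raises, naming the sample.
    """
    X = np.asarray(percent_matrix, float).T
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    sds = X.std(axis=1)
    if np.any(sds == 0):
        i = int(np.argmax(sds == 0))
        name = sample_ids[i] if sample_ids else f"sample {i}"
        raise ValueError(f"zero-variance methylation profile for {name}; "
                         "correlation distance undefined")
    dist = 1.0 - np.corrcoef(X)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return linkage(squareform(dist, checks=False), method="ward")


def scaffold_dm_density(dm_sites: pd.DataFrame, scaffold_lengths: dict[str, int]):
    """Per-scaffold DM counts and their correlation with scaffold length.

    Correlations (Pearson and Spearman, with p) require >= 3 scaffolds and at
    least one DM site; otherwise only counts are returned.
    """
    counts = pd.Series(0, index=list(scaffold_lengths), dtype=int)
    if len(dm_sites):
        vc = dm_sites["scaffold"].value_counts()
        counts.loc[vc.index.intersection(counts.index)] = vc
    table = pd.DataFrame({"scaffold": counts.index,
                          "length": [scaffold_lengths[s] for s in counts.index],
                          "n_dm": counts.to_numpy()})
    summary = None
    if (len(table) >= 3 and table["n_dm"].sum() > 0
            and table["n_dm"].nunique() > 1 and table["length"].nunique() > 1):
        pr = stats.pearsonr(table["length"], table["n_dm"])
        sr = stats.spearmanr(table["length"], table["n_dm"])
        summary = {"pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
                   "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue)}
    return table, summary
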