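"""Call-level filtering cascade producing the analysis-ready united matrix.

The cascade mirrors the standard WGBS workflow: per-sample coverage filtering
(minimum depth and a high-coverage percentile cut against paralogs/repeats),
median coverage normalization across samples, strict intersection ("unite")
of sites covered in every sample, and masking of CpGs that overlap SNPs so
that only methylation — not C>T polymorphism — drives downstream signal.
Every stage emits a :class:`FilterReport` so counts are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .meth_io import SampleMethylome


@dataclass
class FilterReport:
    stage: str
    input_sites: int
    removed_low_coverage: int = 0
    removed_high_percentile: int = 0
    removed_snp_overlap: int = 0
    retained: int = 0

    def check(self) -> None:
        removed = (self.removed_low_coverage + self.removed_high_percentile
                   + self.removed_snp_overlap)
        if self.input_sites != removed + self.retained:
            raise AssertionError(f"filter report not conserved at stage {self.stage}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class UnitedMatrix:
    """Dense sites x samples matrix of (coverage, meth count); no missing cells.

    ``sites`` has columns scaffold, position, strand, aligned row-wise with the
    count arrays.
    """

    sites: pd.DataFrame
    coverage: np.ndarray  # (n_sites, n_samples)
    meth: np.ndarray      # (n_sites, n_samples)
    samples: list[str]
    populations: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def percent(self) -> np.ndarray:
        """Per-site per-sample % methylation (100 * meth / coverage)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.meth / self.coverage

    def population_index(self) -> dict[str, np.ndarray]:
        pops = np.asarray(self.populations)
        return {p: np.flatnonzero(pops == p) for p in dict.fromkeys(self.populations)}

    def subset_sites(self, mask: np.ndarray) -> "UnitedMatrix":
        return UnitedMatrix(self.sites.loc[mask].reset_index(drop=True),
                            self.coverage[mask], self.meth[mask],
                            list(self.samples), list(self.populations))


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("empty vector")
    k = int(np.ceil(pct / 100.0 * v.size))
    return float(v[min(max(k, 1), v.size) - 1])


def filter_coverage(methylome: SampleMethylome, min_cov: int = 10,
                    upper_pct: float | None = 99.0):
    """Drop records below ``min_cov`` or above the per-sample coverage percentile.

    The percentile is computed on this sample's own coverage distribution
    (nearest-rank); records strictly above it are removed.  Returns the
    filtered methylome and a :class:`FilterReport`.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    rec = methylome.records
    cov = rec["coverage"].to_numpy()
    low = cov < min_cov
    if upper_pct is not None and cov.size:
        cut = nearest_rank_percentile(cov, upper_pct)
        high = (cov > cut) & ~low
    else:
        high = np.zeros_like(low)
    keep = ~(low | high)
    report = FilterReport(stage=f"coverage:{methylome.sample_id}",
                          input_sites=int(cov.size),
                          removed_low_coverage=int(low.sum()),
                          removed_high_percentile=int(high.sum()),
                          retained=int(keep.sum()))
    report.check()
    out = SampleMethylome(methylome.sample_id, methylome.population,
                          rec.loc[keep].reset_index(drop=True))
    return out, report


def normalize_coverage_median(methylomes: list[SampleMethylome]) -> list[SampleMethylome]:
    """Scale each sample's coverage so sample medians match their joint median.

    factor_s = median(all sample medians) / median_s; new coverage and meth
    counts are rounded so the per-site %methylation is preserved to rounding.
    """
    if len(methylomes) < 2:
        raise ValueError("need >= 2 samples to normalize")
    medians = np.array([np.median(m.records["coverage"]) for m in methylomes], float)
    if np.any(medians == 0):
        raise ValueError("zero median coverage in a sample")
    target = float(np.median(medians))
    out = []
    for m, med in zip(methylomes, medians):
        f = target / med
        rec = m.records.copy()
        old_cov = rec["coverage"].to_numpy(float)
        old_pct = np.where(old_cov > 0, rec["count_meth"].to_numpy(float) / old_cov, 0.0)
        new_cov = np.rint(f * old_cov).astype(int)
        new_meth = np.rint(new_cov * old_pct).astype(int)
        rec["coverage"] = new_cov
        rec["count_meth"] = new_meth
        rec["count_unmeth"] = new_cov - new_meth
        out.append(SampleMethylome(m.sample_id, m.population, rec))
    return out


def unite_samples(methylomes: list[SampleMethylome], min_cov: int = 10) -> UnitedMatrix:
    """Strict intersection of (scaffold, position, strand) keys across samples.

    Only sites covered at >= ``min_cov`` in *every* sample survive (the minimum
    is re-checked after normalization rounding).  An empty intersection yields
    an empty matrix, not an exception.
    """
    if len(methylomes) < 2:
        raise ValueError("need >= 2 samples to unite")
    keyed = []
    for m in methylomes:
        rec = m.records
        ok = rec["coverage"] >= min_cov
        df = rec.loc[ok].set_index(["scaffold", "position", "strand"])
        keyed.append(df[["coverage", "count_meth"]])
    common = keyed[0].index
    for df in keyed[1:]:
        common = common.intersection(df.index)
    common = common.sortlevel()[0] if len(common) else common
    n = len(common)
    coverage = np.zeros((n, len(methylomes)), dtype=np.int64)
    meth = np.zeros_like(coverage)
    for j, df in enumerate(keyed):
        sub = df.loc[common] if n else df.iloc[:0]
        coverage[:, j] = sub["coverage"].to_numpy()
        meth[:, j] = sub["count_meth"].to_numpy()
    sites = pd.DataFrame(list(common), columns=["scaffold", "position", "strand"]) \
        if n else pd.DataFrame(columns=["scaffold", "position", "strand"])
    return UnitedMatrix(sites=sites, coverage=coverage, meth=meth,
                        samples=[m.sample_id for m in methylomes],
                        populations=[m.population for m in methylomes])


def mask_snp_sites(matrix: UnitedMatrix, snp_sites, ct_only: bool = False):
    """Remove united sites whose (scaffold, position) overlaps a SNP.

    By default any biallelic SNP position masks the site (conservative
    superset); ``ct_only`` restricts masking to C>T / G>A variants.
    """
    if ct_only:
        positions = {(c, p) for (c, p, ref, alt) in snp_sites
                     if (ref, alt) in (("C", "T"), ("G", "A"))}
    else:
        positions = {(c, p) for (c, p, *_rest) in snp_sites}
    keys = list(zip(matrix.sites["scaffold"], matrix.sites["position"]))
    keep = np.array([k not in positions for k in keys], dtype=bool) \
        if keys else np.zeros(0, dtype=bool)
    report = FilterReport(stage="snp_mask", input_sites=matrix.n_sites,
                          removed_snp_overlap=int((~keep).sum()) if keys else 0,
                          retained=int(keep.sum()) if keys else 0)
    report.check()
    return matrix.subset_sites(keep), report


def conversion_efficiency(spikein: SampleMethylome,
                          call_threshold_pct: float = 10.0) -> tuple[float, float]:
    """Bisulfite conversion QC on an unmethylated spike-in control genome.

    Returns ``(raw_rate, false_methylated_fraction)`` in percent: the raw
    conversion rate is the fraction of reads calling T (unmethylated), and the
    false-methylated fraction is the share of sites whose %methylation meets a
    liberal call threshold (default 10%).
    """
    rec = spikein.records
    total = int(rec["coverage"].sum())
    if total == 0:
        raise ValueError("spike-in has zero total coverage")
    raw_rate = 100.0 * rec["count_unmeth"].sum() / total
    pct = spikein.percent_meth()
    false_frac = 100.0 * np.count_nonzero(pct >= call_threshold_pct) / len(rec)
    return float(raw_rate), float(false_frac)
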