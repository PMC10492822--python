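"""Characterization of consistent CpG methylation.

Covers the descriptive half of the pipeline: per-site percent methylation and
its three-class categorization (unmethylated < 10%, sparsely methylated
10-50%, highly methylated >= 50%), a prioritized genomic feature track
(CDS > exon UTR > intron > lncRNA > TE > upstream flank > downstream flank >
intergenic), feature and exon/intron-rank breakdowns of each class,
signed distances to the nearest transcription start site, a two-sample KS
comparison of distance distributions, and Yates-corrected chi-square feature
enrichment with BH correction.

Class boundaries resolve the half-open convention as [0,10) unmethylated,
[10,50) sparse, [50,100] high; exactly 50% is "high".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet
from .meth_io import GeneModel, Transcript
from .site_filtering import UnitedMatrix

CLASS_NAMES = ["unmethylated", "sparse", "high"]

FEATURE_PRECEDENCE = ["CDS", "exon_UTR", "intron", "lncRNA", "TE",
                      "upstream_flank", "downstream_flank", "intergenic"]


@dataclass
class FeatureTrack:
    """Prioritized interval sets; every position resolves to exactly one class."""

    classes: dict[str, IntervalSet]
    scaffold_lengths: dict[str, int] | None = None
    precedence: list[str] = field(default_factory=lambda: list(FEATURE_PRECEDENCE))


def percent_methylation(matrix: UnitedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site per-sample %methylation and the unweighted per-site mean."""
    pct = matrix.percent()
    return pct, pct.mean(axis=1)


def classify_sites(means: np.ndarray, low: float = 10.0, high: float = 50.0) -> np.ndarray:
    """Three-class categorization of per-site mean %methylation.

    unmethylated: mean < low; sparse: low <= mean < high; high: mean >= high.
    """
    if low >= high:
        raise ValueError("low boundary must be below high boundary")
    means = np.asarray(means, dtype=float)
    out = np.full(means.shape, "unmethylated", dtype=object)
    out[means >= low] = "sparse"
    out[means >= high] = "high"
    return out


def sample_summary(matrix: UnitedMatrix) -> pd.DataFrame:
    """Per-sample and per-population mean %methylation with SD.

    Population mean is the mean over its samples' per-sample means; population
    SD is across those sample means (ddof=1, 0 for a single sample).
    """
    pct = matrix.percent()
    rows = []
    sample_means = pct.mean(axis=0)
    for sid, pop, m, s in zip(matrix.samples, matrix.populations,
                              sample_means, pct.std(axis=0, ddof=1)):
        rows.append({"level": "sample", "name": sid, "population": pop,
                     "mean_pct": float(m), "sd_pct": float(s)})
    pops = pd.Series(matrix.populations)
    for pop in dict.fromkeys(matrix.populations):
        idx = np.flatnonzero((pops == pop).to_numpy())
        vals = sample_means[idx]
        rows.append({"level": "population", "name": pop, "population": pop,
                     "mean_pct": float(vals.mean()),
                     "sd_pct": float(vals.std(ddof=1)) if vals.size > 1 else 0.0})
    return pd.DataFrame(rows)


def build_feature_track(genes: list[GeneModel], lnc_genes=(), te_intervals=(),
                        scaffold_lengths: dict[str, int] | None = None,
                        flank: int = 1000) -> FeatureTrack:
    """Construct the prioritized feature track from gene models.

    CDS and exon-UTR intervals come from transcript structure; introns are the
    exon complement within genes; ``flank``-bp up/downstream flanks attach to
    the gene span by strand; residual sequence is intergenic (resolved at
    annotation time, no explicit interval set needed).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    classes = {name: IntervalSet() for name in FEATURE_PRECEDENCE if name != "intergenic"}
    for g in genes:
        for tx in g.transcripts:
            for s, e in tx.cds:
                classes["CDS"].add(g.scaffold, s, e)
            for s, e in tx.utr():
                classes["exon_UTR"].add(g.scaffold, s, e)
            for s, e in tx.introns():
                classes["intron"].add(g.scaffold, s, e)
    for g in lnc_genes:
        classes["lncRNA"].add(g.scaffold, g.start, g.end)
    for scaffold, s, e in te_intervals:
        classes["TE"].add(scaffold, s, e)
    for g in list(genes) + list(lnc_genes):
        length = (scaffold_lengths or {}).get(g.scaffold)
        up = (g.start - flank, g.start - 1) if g.strand == "+" else (g.end + 1, g.end + flank)
        down = (g.end + 1, g.end + flank) if g.strand == "+" else (g.start - flank, g.start - 1)
        for name, (s, e) in (("upstream_flank", up), ("downstream_flank", down)):
            s = max(s, 1)
            if length is not None:
                e = min(e, length)
            if e >= s:
                classes[name].add(g.scaffold, s, e)
    return FeatureTrack(classes=classes, scaffold_lengths=scaffold_lengths)


def annotate_sites(sites: pd.DataFrame, track: FeatureTrack) -> np.ndarray:
    """Assign each site exactly one feature class by precedence."""
    labels = np.full(len(sites), "intergenic", dtype=object)
    if track.scaffold_lengths:
        for scaffold, grp in sites.groupby("scaffold", sort=False):
            if scaffold not in track.scaffold_lengths:
                raise ValueError(f"site scaffold {scaffold!r} not in scaffold lengths")
            pos = grp["position"].to_numpy()
            if (pos < 1).any() or (pos > track.scaffold_lengths[scaffold]).any():
                raise ValueError(f"site position off scaffold {scaffold!r}")
    unassigned = np.ones(len(sites), dtype=bool)
    for name in track.precedence:
        if name == "intergenic" or name not in track.classes:
            continue
        iset = track.classes[name]
        for scaffold, grp in sites.groupby("scaffold", sort=False):
            idx = grp.index.to_numpy()
            cand = idx[unassigned[idx]]
            if cand.size == 0:
                continue
            hit = iset.contains(scaffold, sites["position"].to_numpy()[cand])
            labels[cand[hit]] = name
            unassigned[cand[hit]] = False
    return labels


def feature_breakdown(classes: np.ndarray, features: np.ndarray) -> pd.DataFrame:
    """Class x feature counts, within-class percentages, and relative rates.

    ``pct_of_class`` sums to 100 across features within each methylation class;
    ``relative_pct`` is 100 * (class sites in feature) / (all CpGs in feature).
    """
    classes = np.asarray(classes)
    features = np.asarray(features)
    feat_names = list(FEATURE_PRECEDENCE)
    all_counts = {f: int((features == f).sum()) for f in feat_names}
    rows = []
    for cls in CLASS_NAMES + ["all"]:
        in_cls = np.ones(len(classes), bool) if cls == "all" else classes == cls
        total = int(in_cls.sum())
        for f in feat_names:
            n = int((in_cls & (features == f)).sum())
            rows.append({
                "class": cls, "feature": f, "count": n,
                "pct_of_class": 100.0 * n / total if total else 0.0,
                "relative_pct": 100.0 * n / all_counts[f] if all_counts[f] else 0.0,
            })
    return pd.DataFrame(rows)


def chisq_feature_enrichment(classes: np.ndarray, features: np.ndarray,
                             target_class: str = "high") -> pd.DataFrame:
    """Per-feature Yates-corrected chi-square of target-class sites vs all CpGs.

    For each feature a 2x2 table (in-feature vs not) x (target class vs all
    CpGs) is tested with continuity correction, df=1; p-values are BH-adjusted
    across the features.  Expected cells < 1 are flagged, not fatal.
    """
    classes = np.asarray(classes)
    features = np.asarray(features)
    in_cls = classes == target_class
    rows = []
    for f in FEATURE_PRECEDENCE:
        in_f = features == f
        table = np.array([[int((in_cls & in_f).sum()), int((in_cls & ~in_f).sum())],
                          [int(in_f.sum()), int((~in_f).sum())]], dtype=float)
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            rows.append({"feature": f, "statistic": np.nan, "p": np.nan,
                         "low_expected": True})
            continue
        res = stats.chi2_contingency(table, correction=True)
        rows.append({"feature": f, "statistic": float(res[0]), "p": float(res[1]),
                     "low_expected": bool((res[3] < 1).any())})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["q"] = q
    return df


def yates_chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Yates continuity-corrected chi-square for a 2x2 table; (X2, p)."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table, float), correction=True)
    return float(stat), float(p)


def longest_isoform(genes: list[GeneModel]) -> dict[str, Transcript]:
    """One transcript per gene: maximal summed exon length, ties to smallest ID."""
    out = {}
    for g in genes:
        if not g.transcripts:
            continue
        out[g.gene_id] = min(g.transcripts, key=lambda t: (-t.exon_length, t.tx_id))
    return out


def _ranked_gene_intervals(gene: GeneModel, tx: Transcript):
    """(start, end, kind, rank) in transcription direction; rank 1 = 5' most."""
    exons = sorted(tx.exons)
    introns = tx.introns()
    if gene.strand == "-":
        exons = exons[::-1]
        introns = introns[::-1]
    out = [(s, e, "exon", i + 1) for i, (s, e) in enumerate(exons)]
    out += [(s, e, "intron", i + 1) for i, (s, e) in enumerate(introns)]
    return out


def exon_intron_rank_breakdown(sites: pd.DataFrame, classes: np.ndarray,
                               genes: list[GeneModel],
                               isoforms: dict[str, Transcript] | None = None
                               ) -> pd.DataFrame:
    """Counts of each methylation class per exon/intron rank (longest isoform).

    Ranks are numbered 1..k in transcription direction; ``relative_pct`` is
    100 * class count / all-CpG count at that rank.
    """
    if isoforms is None:
        isoforms = longest_isoform(genes)
    classes = np.asarray(classes)
    by_scaffold: dict[str, list] = {}
    for g in genes:
        tx = isoforms.get(g.gene_id)
        if tx is None:
            continue
        by_scaffold.setdefault(g.scaffold, []).extend(_ranked_gene_intervals(g, tx))
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for scaffold, grp in sites.groupby("scaffold", sort=False):
        ivals = by_scaffold.get(scaffold)
        if not ivals:
            continue
        ivals.sort()
        starts = np.array([iv[0] for iv in ivals])
        ends = np.array([iv[1] for iv in ivals])
        pos = grp["position"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
        for row_i, iv_i in zip(grp.index.to_numpy()[ok], idx[ok]):
            _, _, kind, rank = ivals[iv_i]
            d = counts.setdefault((kind, rank),
                                  {c: 0 for c in CLASS_NAMES} | {"total": 0})
            d[classes[row_i]] += 1
            d["total"] += 1
    rows = []
    for (kind, rank), d in sorted(counts.items()):
        for cls in CLASS_NAMES:
            rows.append({"kind": kind, "rank": rank, "class": cls,
                         "count": d[cls], "total_cpgs": d["total"],
                         "relative_pct": 100.0 * d[cls] / d["total"] if d["total"] else 0.0})
    return pd.DataFrame(rows, columns=["kind", "rank", "class", "count",
                                       "total_cpgs", "relative_pct"])


def tss_distances(sites: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Signed distance from each site to the nearest TSS on its scaffold.

    Downstream of the owning gene's transcription direction is positive;
    distance 0 counts as downstream.  Nearest is by absolute genomic distance;
    exact ties between two TSS resolve toward the lower scaffold coordinate
    and are flagged in the ``tie`` column.  Sites on gene-less scaffolds get
    NaN distance.
    """
    tss_by_scaffold: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for scaffold in {g.scaffold for g in genes}:
        gs = [g for g in genes if g.scaffold == scaffold]
        pos = np.array([g.tss for g in gs])
        strands = np.array([1 if g.strand == "+" else -1 for g in gs])
        order = np.argsort(pos, kind="mergesort")
        tss_by_scaffold[scaffold] = (pos[order], strands[order])
    dist = np.full(len(sites), np.nan)
    tie = np.zeros(len(sites), dtype=bool)
    for scaffold, grp in sites.groupby("scaffold", sort=False):
        if scaffold not in tss_by_scaffold:
            continue
        tss, strands = tss_by_scaffold[scaffold]
        pos = grp["position"].to_numpy()
        right = np.searchsorted(tss, pos, side="left")
        left = right - 1
        d_left = np.where(left >= 0, np.abs(pos - tss[np.clip(left, 0, None)]), np.inf)
        d_right = np.where(right < len(tss),
                           np.abs(tss[np.clip(right, 0, len(tss) - 1)] - pos), np.inf)
        use_left = d_left <= d_right  # tie -> lower coordinate
        chosen = np.where(use_left, np.clip(left, 0, None),
                          np.clip(right, 0, len(tss) - 1))
        signed = (pos - tss[chosen]) * strands[chosen]
        idx = grp.index.to_numpy()
        dist[idx] = signed
        tie[idx] = np.isfinite(d_left) & (d_left == d_right)
    out = sites[["scaffold", "position"]].copy()
    out["distance"] = dist
    out["tie"] = tie
    return out


def tss_summary(distances: np.ndarray) -> dict:
    """Mean |distance|, signed mean, downstream/upstream counts and ratio."""
    d = np.asarray(distances, float)
    d = d[np.isfinite(d)]
    down = int((d >= 0).sum())
    up = int((d < 0).sum())
    return {
        "n": int(d.size),
        "mean_abs_distance": float(np.abs(d).mean()) if d.size else np.nan,
        "mean_signed_distance": float(d.mean()) if d.size else np.nan,
        "n_downstream": down,
        "n_upstream": up,
        "downstream_upstream_ratio": down / up if up else np.inf,
    }


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample KS test: (D, asymptotic p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires nonempty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
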