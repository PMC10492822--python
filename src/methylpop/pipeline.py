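"""End-to-end stage orchestration.

Each ``run_*`` function wires the library stages together exactly as the
analysis is meant to be run: simulate -> characterize (filter/unite/mask,
classify, annotate, ranks, TSS, enrichment) -> differential methylation
(variability filter, corrected chi-square, BH, calls, PCA/clustering) ->
popgen + integration (pi / F_ST windows, window table, correlations,
ZINB/ZIBB fits).  All thresholds default to the analysis' standard values
and every stage returns its tables so drivers can write them out.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
import pandas as pd

from . import differential_methylation as dm
from . import methylome_profile as profile
from . import popgen_stats as pg
from . import site_filtering as filt
from . import synthetic_data as sim
from . import window_integration as integ
from . import meth_io


@dataclasses.dataclass
class PipelineConfig:
    """Stage parameters with their standard defaults."""

    min_coverage: int = 10
    upper_percentile: float = 99.0
    class_low: float = 10.0
    class_high: float = 50.0
    sd_min: float = 2.0
    q_max: float = 0.01
    diff_min: float = 10.0
    window_size: int = 1000
    n_boot: int = 1000
    flank: int = 1000
    focal_pop: str = "OR"
    meth_window_threshold: float = 10.0
    seed: int = 0


def run_simulate(config: sim.SimConfig, outdir: str) -> dict:
    """Generate the full fixture set with truth tables and a manifest."""
    genome, meth_truth, samples, pop_truth, spikein = sim.simulate_all(config)
    return sim.write_fixture_set(genome, meth_truth, samples, pop_truth,
                                 config, outdir, spikein=spikein)


def load_fixture_dir(directory: str):
    """Read a written fixture set back through the meth_io readers."""
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    pops = manifest["config"]["pop_names"]
    samples = []
    for fname in manifest["files"]["calls"]:
        sid = fname.replace(".methylkit.txt", "")
        pop = next(p for p in pops if sid.startswith(p))
        samples.append(meth_io.read_methylkit_file(
            os.path.join(directory, fname), sample_id=sid, population=pop))
    genes, lnc, te = meth_io.read_gff3(os.path.join(directory, "annotation.gff3"))
    snps = meth_io.read_vcf_sites(os.path.join(directory, "snps.vcf"))
    lengths = meth_io.read_scaffold_lengths(
        os.path.join(directory, "scaffold_lengths.tsv"))
    genotypes = pg.read_genotype_table(os.path.join(directory, "genotypes.tsv"))
    return {"samples": samples, "genes": genes, "lnc_genes": lnc,
            "te_intervals": te, "snps": snps, "scaffold_lengths": lengths,
            "genotypes": genotypes, "manifest": manifest}


def build_united(samples, snps, cfg: PipelineConfig):
    """Coverage filter -> median normalization -> unite -> SNP mask."""
    reports = []
    filtered = []
    for m in samples:
        f, rep = filt.filter_coverage(m, min_cov=cfg.min_coverage,
                                      upper_pct=cfg.upper_percentile)
        filtered.append(f)
        reports.append(rep)
    normalized = filt.normalize_coverage_median(filtered)
    united = filt.unite_samples(normalized, min_cov=cfg.min_coverage)
    masked, mask_rep = filt.mask_snp_sites(united, snps)
    reports.append(mask_rep)
    return masked, reports


def run_characterize(samples, genes, lnc_genes, te_intervals, snps,
                     scaffold_lengths, cfg: PipelineConfig | None = None) -> dict:
    """Filtering cascade plus the consistent-methylation profile."""
    cfg = cfg or PipelineConfig()
    matrix, reports = build_united(samples, snps, cfg)
    pct, mean_pct = profile.percent_methylation(matrix)
    classes = profile.classify_sites(mean_pct, low=cfg.class_low, high=cfg.class_high)
    track = profile.build_feature_track(genes, lnc_genes, te_intervals,
                                        scaffold_lengths=scaffold_lengths,
                                        flank=cfg.flank)
    features = profile.annotate_sites(matrix.sites, track)
    breakdown = profile.feature_breakdown(classes, features)
    enrichment = profile.chisq_feature_enrichment(classes, features, "high")
    isoforms = profile.longest_isoform(genes)
    ranks = profile.exon_intron_rank_breakdown(matrix.sites, classes, genes, isoforms)
    lnc_iso = profile.longest_isoform(lnc_genes)
    lnc_ranks = profile.exon_intron_rank_breakdown(matrix.sites, classes,
                                                   lnc_genes, lnc_iso)
    tss = profile.tss_distances(matrix.sites, genes + lnc_genes)
    d = tss["distance"].to_numpy()
    high_mask = classes == "high"
    ks = None
    if high_mask.any() and np.isfinite(d).any():
        ks = profile.ks_two_sample(d[np.isfinite(d) & high_mask],
                                   d[np.isfinite(d)])
    return {
        "matrix": matrix, "reports": reports, "percent": pct,
        "mean_pct": mean_pct, "classes": classes, "track": track,
        "features": features, "breakdown": breakdown,
        "enrichment": enrichment, "ranks": ranks, "lnc_ranks": lnc_ranks,
        "tss": tss, "tss_summary_all": profile.tss_summary(d),
        "tss_summary_high": profile.tss_summary(d[high_mask]),
        "ks_high_vs_all": ks,
        "sample_summary": profile.sample_summary(matrix),
    }


def run_diffmeth(matrix, pop1: str, pop2: str,
                 cfg: PipelineConfig | None = None) -> dict:
    """SD filter -> corrected chi-square -> BH -> calls -> structure views."""
    cfg = cfg or PipelineConfig()
    pct = matrix.percent()
    vf = dm.variability_filter(pct, sd_min=cfg.sd_min)
    sub = matrix.subset_sites(vf.retained)
    tests = dm.dm_test(sub, pop1, pop2)
    tests["q"] = dm.bh_fdr(tests["p"].to_numpy())
    calls = dm.call_dm_sites(tests, focal_pop=cfg.focal_pop, pop1=pop1, pop2=pop2,
                             q_max=cfg.q_max, diff_min=cfg.diff_min)
    calls = pd.concat([sub.sites.reset_index(drop=True), calls], axis=1)
    coords, varfrac = dm.pca_samples(sub.percent())
    link = dm.cluster_samples(sub.percent(), sample_ids=sub.samples)
    return {"variability": vf, "matrix": sub, "calls": calls,
            "summary": dm.dm_summary(calls), "pca_coords": coords,
            "pca_varfrac": varfrac, "linkage": link}


def run_popgen(genotypes: pg.GenotypeMatrix, scaffold_lengths: dict,
               pop1: str, pop2: str, cfg: PipelineConfig | None = None) -> dict:
    """pi and Hudson F_ST per site and per 1-kb window, with bootstrap CIs."""
    cfg = cfg or PipelineConfig()
    rows = genotypes.population_rows()
    j_all, n_all = genotypes.allele_counts()
    site_pi = pg.pi_per_site(j_all, n_all)
    windows = pg.window_grid(scaffold_lengths, cfg.window_size)
    wi = pg.assign_windows(genotypes.scaffolds, genotypes.positions, windows)
    pi_win = pg.pi_windows(site_pi, wi, windows)
    j1, n1 = genotypes.allele_counts(rows[pop1])
    j2, n2 = genotypes.allele_counts(rows[pop2])
    ok = (n1 >= 2) & (n2 >= 2)
    num = np.zeros(genotypes.n_sites)
    den = np.zeros(genotypes.n_sites)
    num[ok], den[ok] = pg.hudson_fst_site(j1[ok] / n1[ok], n1[ok],
                                          j2[ok] / n2[ok], n2[ok])
    fst_win = pg.fst_windows(num, den, wi, windows)
    fst_global = pg.fst_ratio_of_sums(num, den)
    pi_ci = pg.bootstrap_ci(pi_win["pi"].to_numpy(), n_boot=cfg.n_boot,
                            seed=cfg.seed)
    comp = fst_win[["fst_num", "fst_den"]].to_numpy()
    fst_ci = pg.bootstrap_ci(
        comp, statistic=lambda v: pg.fst_ratio_of_sums(v[:, 0], v[:, 1]),
        n_boot=cfg.n_boot, seed=cfg.seed + 1)
    coords, varfrac = pg.genotype_pca(genotypes)
    diversity = pi_win.merge(fst_win[["scaffold", "start", "fst_num", "fst_den", "fst"]],
                             on=["scaffold", "start"])
    return {"site_pi": site_pi, "windows": diversity, "fst_global": fst_global,
            "pi_ci": pi_ci, "fst_ci": fst_ci, "pca_coords": coords,
            "pca_varfrac": varfrac, "window_index": wi}


def run_integrate(char: dict, dm_calls: pd.DataFrame, popgen: dict,
                  scaffold_lengths: dict, cfg: PipelineConfig | None = None) -> dict:
    """Join the 1-kb methylation and diversity summaries and fit the models."""
    cfg = cfg or PipelineConfig()
    matrix = char["matrix"]
    wi = pg.assign_windows(matrix.sites["scaffold"].to_numpy(),
                           matrix.sites["position"].to_numpy(),
                           popgen["windows"][["scaffold", "start", "end"]])
    absdiff = None
    if dm_calls is not None and {"pct_pop1", "pct_pop2"} <= set(dm_calls.columns):
        keyed = dm_calls.set_index(["scaffold", "position", "strand"])
        site_key = pd.MultiIndex.from_frame(matrix.sites)
        sub = keyed.reindex(site_key)
        absdiff = np.abs((sub["pct_pop2"] - sub["pct_pop1"]).to_numpy(float))
        absdiff = np.nan_to_num(absdiff, nan=0.0)
    table = integ.build_window_table(matrix.sites, char["mean_pct"],
                                     char["classes"], wi, popgen["windows"],
                                     site_absdiff=absdiff)
    cors = {
        "nhigh_vs_pi": integ.correlations(table["n_high"], table["pi"]),
        "prophigh_vs_pi": integ.correlations(table["prop_high"], table["pi"]),
        "meanmeth_vs_nhigh": integ.correlations(table["mean_pct_meth"],
                                                table["n_high"]),
    }
    if "mean_abs_diff" in table.columns and table["fst"].notna().any():
        ok = table["fst"].notna() & table["mean_abs_diff"].notna()
        if ok.sum() >= 3:
            cors["fst_vs_absdiff"] = integ.correlations(
                table.loc[ok, "fst"], table.loc[ok, "mean_abs_diff"])
    zinb = integ.zinb_fit(table["n_high"].to_numpy(), table["log_pi"].to_numpy())
    zibb = integ.zibb_fit(table["n_high"].to_numpy(), table["n_cpgs"].to_numpy(),
                          table["log_pi"].to_numpy())
    retained = integ.exclude_unmethylated_windows(
        table, char["mean_pct"], wi, threshold=cfg.meth_window_threshold)
    cors_excl = None
    if ("mean_abs_diff" in retained.columns and len(retained) >= 3
            and retained["fst"].notna().sum() >= 3):
        ok = retained["fst"].notna() & retained["mean_abs_diff"].notna()
        if ok.sum() >= 3:
            cors_excl = integ.correlations(retained.loc[ok, "fst"],
                                           retained.loc[ok, "mean_abs_diff"])
    return {"table": table, "correlations": cors, "zinb": zinb, "zibb": zibb,
            "retained_methylated": retained,
            "fst_vs_absdiff_excl": cors_excl, "window_index": wi}
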