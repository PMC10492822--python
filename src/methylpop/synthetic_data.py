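"""Synthetic insect methylome generator with known ground truth.

Emulates, at desk scale, the structure the analysis assumes for a bumble-bee
style genome: sparse global CpG methylation (~1%) concentrated in coding
sequence with an exon-rank bias (first exon low, exons 2-4 high, decaying
after), bimodal per-site methylation levels (a beta mixture of a background
and a methylated component), population-biased hypomethylation at a minority
of differentially methylated sites, C>T SNPs overlapping CpGs, weak
population structure (Balding-Nichols F), and a negative log-linear coupling
between windowed methylation density and nucleotide diversity.

Every quantity downstream stages estimate is recorded as truth so recovery
is testable: gene/feature intervals, per-site methylation levels per
population with DM flags and directions, SNP frequencies and genotypes, and
per-window theta.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .meth_io import (GeneModel, SampleMethylome, Transcript, RECORD_COLUMNS,
                      write_methylkit_file)
from .methylome_profile import (FeatureTrack, build_feature_track,
                                _ranked_gene_intervals)
from .popgen_stats import GenotypeMatrix, window_grid, assign_windows

DEFAULT_CPG_DENSITY = {
    "CDS": 0.030, "exon_UTR": 0.025, "intron": 0.020, "lncRNA": 0.020,
    "TE": 0.015, "upstream_flank": 0.020, "downstream_flank": 0.020,
    "intergenic": 0.015,
}

#: probability a CpG is in the methylated state, by feature class
DEFAULT_W_HIGH = {
    "CDS": 0.09, "exon_UTR": 0.015, "intron": 0.0017, "lncRNA": 0.005,
    "TE": 0.001, "upstream_flank": 0.002, "downstream_flank": 0.002,
    "intergenic": 0.0004,
}

#: exon-rank multipliers for exonic CpGs (rank 1 low, 2-4 peak, then decay);
#: shaped like the relative-percentage profile of insect gene-body methylation
DEFAULT_W_HIGH_EXON_RANK = (0.014, 0.101, 0.126, 0.102, 0.07, 0.05, 0.035, 0.025)


@dataclass
class SimConfig:
    """All knobs for the generator; defaults are the study conditions."""

    seed: int = 0
    n_scaffolds: int = 6
    scaffold_length: int = 150_000
    n_genes: int = 42
    n_lncrnas: int = 6
    n_tes: int = 12
    te_length_mean: int = 500
    exon_count_mean: float = 6.0
    exon_length_mean: int = 200
    intron_length_mean: int = 1500
    utr_length: int = 80
    flank_size: int = 1000
    cpg_density: dict = field(default_factory=lambda: dict(DEFAULT_CPG_DENSITY))
    w_high: dict = field(default_factory=lambda: dict(DEFAULT_W_HIGH))
    w_high_exon_rank: tuple = DEFAULT_W_HIGH_EXON_RANK
    beta_high: tuple = (8.0, 2.0)
    beta_low: tuple = (0.5, 100.0)
    n_samples_per_pop: int = 4
    coverage_mean: float = 75.0
    coverage_dispersion: float = 10.0
    sample_rho: float = 0.05
    f_dm: float = 0.3
    delta_dm: float = 20.0        # percentage points
    p_hypo: float = 0.876
    n_snps: int = 5000
    p_snp_at_cpg: float = 0.04
    fst_truth: float = 0.025
    n_indiv_per_pop: int = 8
    theta_base: float = 0.002
    theta_meth_slope: float = -3.0
    window_size: int = 1000
    conversion_rate: float = 0.998
    spikein_sites: int = 2000
    pop_names: tuple = ("CA", "OR")  # focal (pop2) is the high-elevation OR

    def validate(self) -> None:
        probs = [self.sample_rho, self.f_dm, self.p_hypo, self.p_snp_at_cpg,
                 self.fst_truth, self.conversion_rate, *self.w_high.values(),
                 *self.w_high_exon_rank]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not (0 <= self.sample_rho < 1):
            raise ValueError("sample_rho must be in [0, 1)")
        if any(a <= 0 for a in (*self.beta_high, *self.beta_low)):
            raise ValueError("beta shape parameters must be > 0")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if not (0 < self.delta_dm <= 100):
            raise ValueError("delta_dm must be in (0, 100]")
        if any(d < 0 for d in self.cpg_density.values()):
            raise ValueError("cpg_density must be >= 0")


@dataclass
class GenomeTruth:
    scaffolds: dict
    genes: list
    lnc_genes: list
    te_intervals: list
    track: FeatureTrack
    cpg: pd.DataFrame  # scaffold, position, strand, feature, kind, rank


@dataclass
class MethTruth:
    sites: pd.DataFrame  # scaffold, position, strand, level_pop1, level_pop2,
                         # dm_flag, dm_direction ('hypo'/'hyper'/'')


@dataclass
class PopTruth:
    snps: pd.DataFrame       # scaffold, position, ref, alt, at_cpg, p_anc, p_pop1, p_pop2
    genotypes: GenotypeMatrix
    window_theta: pd.DataFrame  # scaffold, start, end, theta, meth_density


class SizingError(ValueError):
    """Requested gene/TE content does not fit on the scaffolds."""


def _gene_structure(rng, cfg: SimConfig):
    """Exon/intron lengths for one gene; returns (exon_lens, intron_lens)."""
    k = 1 + rng.poisson(max(cfg.exon_count_mean - 1.0, 0.0))
    exon_lens = np.maximum(30, rng.poisson(cfg.exon_length_mean, size=k))
    intron_lens = (np.maximum(60, rng.poisson(cfg.intron_length_mean, size=k - 1))
                   if k > 1 else np.array([], dtype=int))
    return exon_lens, intron_lens


def simulate_genome(config: SimConfig) -> GenomeTruth:
    """Place non-overlapping genes/lncRNAs/TEs and draw CpG positions.

    Genes get random strands and realized exon/intron structure with terminal
    UTR segments carved from the outer exons; flanks attach at annotation
    time; every CpG is then drawn per final feature class at that class's
    configured density (per-bp Bernoulli).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if np.isscalar(config.scaffold_length):
        lengths = [int(config.scaffold_length)] * config.n_scaffolds
    else:
        lengths = [int(x) for x in config.scaffold_length]
        if len(lengths) != config.n_scaffolds:
            raise ValueError("scaffold_length list must match n_scaffolds")
    scaffolds = {f"scaffold_{i + 1}": L for i, L in enumerate(lengths)}
    names = list(scaffolds)

    # allocate genes/lncRNAs/TEs to scaffolds proportionally to length
    # (largest-remainder), so content density is uniform per bp
    units = (["gene"] * config.n_genes + ["lnc"] * config.n_lncrnas
             + ["te"] * config.n_tes)
    w = np.array(lengths, float)
    w /= w.sum()
    per_scaffold: dict[str, list[str]] = {n: [] for n in names}
    counts = {}
    for kind, total in (("gene", config.n_genes), ("lnc", config.n_lncrnas),
                        ("te", config.n_tes)):
        base = np.floor(w * total).astype(int)
        rem = total - base.sum()
        order = np.argsort(-(w * total - base), kind="mergesort")
        base[order[:rem]] += 1
        counts[kind] = base
    for i, n in enumerate(names):
        per_scaffold[n] = (["gene"] * counts["gene"][i]
                           + ["lnc"] * counts["lnc"][i]
                           + ["te"] * counts["te"][i])

    genes: list[GeneModel] = []
    lnc_genes: list[GeneModel] = []
    te_intervals: list[tuple[str, int, int]] = []
    gap_min = 2 * config.flank_size + 100
    gi = li = ti = 0
    for scaffold in names:
        slots = per_scaffold[scaffold]
        rng.shuffle(slots)
        structures = []
        for u in slots:
            if u == "te":
                structures.append((u, max(100, int(rng.poisson(config.te_length_mean)))))
            else:
                exon_lens, intron_lens = _gene_structure(rng, config)
                structures.append((u, (exon_lens, intron_lens)))
        total = sum(s if u == "te" else int(s[0].sum() + s[1].sum())
                    for u, s in structures)
        budget = scaffolds[scaffold] - total - gap_min * (len(slots) + 1)
        if budget < 0:
            raise SizingError(
                f"{scaffold}: requested content needs more than "
                f"{scaffolds[scaffold]} bp")
        gaps = rng.multinomial(budget, np.ones(len(slots) + 1) / (len(slots) + 1)) \
            if slots else np.array([budget])
        cursor = 1
        for (u, s), gap in zip(structures, gaps[:-1]):
            cursor += gap_min + int(gap)
            if u == "te":
                ti += 1
                te_intervals.append((scaffold, cursor, cursor + s - 1))
                cursor += s
                continue
            exon_lens, intron_lens = s
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = cursor
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el) - 1))
                pos += int(el)
                if i < len(intron_lens):
                    pos += int(intron_lens[i])
            start, end = exons[0][0], exons[-1][1]
            # carve UTR off the transcription-direction outer exon ends
            cds = [list(e) for e in exons]
            u5 = min(config.utr_length, exon_lens[0] - 10)
            u3 = min(config.utr_length, exon_lens[-1] - 10)
            if strand == "+":
                cds[0][0] += max(u5, 0)
                cds[-1][1] -= max(u3, 0)
            else:
                cds[0][0] += max(u3, 0)
                cds[-1][1] -= max(u5, 0)
            cds = [tuple(c) for c in cds if c[1] >= c[0]]
            gid = f"gene_{gi + 1}" if u == "gene" else f"lnc_{li + 1}"
            tx = Transcript(tx_id=f"{gid}.t1", exons=exons,
                            cds=cds if u == "gene" else [])
            model = GeneModel(gene_id=gid, scaffold=scaffold, strand=strand,
                              start=start, end=end, transcripts=[tx],
                              biotype="protein_coding" if u == "gene" else "lncRNA")
            if u == "gene":
                gi += 1
                genes.append(model)
            else:
                li += 1
                lnc_genes.append(model)
            cursor = end + 1

    track = build_feature_track(genes, lnc_genes, te_intervals,
                                scaffold_lengths=scaffolds, flank=config.flank_size)

    # per-bp class codes, then Bernoulli CpG placement per class density
    order = [c for c in track.precedence if c != "intergenic"]
    cpg_rows = []
    for scaffold, length in scaffolds.items():
        codes = np.full(length + 1, "intergenic", dtype=object)
        for name in reversed(order):  # paint low precedence first
            iset = track.classes.get(name)
            if iset is None:
                continue
            for s, e in iset.intervals(scaffold):
                codes[s:min(e, length) + 1] = name
        u = rng.random(length + 1)
        for name, dens in config.cpg_density.items():
            hit = (codes == name) & (u < dens)
            hit[0] = False
            for p in np.flatnonzero(hit):
                cpg_rows.append((scaffold, int(p), "F", codes[p]))
    cpg = pd.DataFrame(cpg_rows, columns=["scaffold", "position", "strand", "feature"])

    # exon/intron rank per CpG (single isoform per gene)
    kind = np.full(len(cpg), "", dtype=object)
    rank = np.zeros(len(cpg), dtype=int)
    by_scaffold: dict[str, list] = {}
    for g in genes + lnc_genes:
        by_scaffold.setdefault(g.scaffold, []).extend(
            _ranked_gene_intervals(g, g.transcripts[0]))
    for scaffold, grp in cpg.groupby("scaffold", sort=False):
        ivals = sorted(by_scaffold.get(scaffold, []))
        if not ivals:
            continue
        starts = np.array([iv[0] for iv in ivals])
        ends = np.array([iv[1] for iv in ivals])
        pos = grp["position"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
        for row_i, iv_i in zip(grp.index.to_numpy()[ok], idx[ok]):
            kind[row_i] = ivals[iv_i][2]
            rank[row_i] = ivals[iv_i][3]
    cpg["kind"] = kind
    cpg["rank"] = rank
    cpg = cpg.sort_values(["scaffold", "position"]).reset_index(drop=True)
    return GenomeTruth(scaffolds=scaffolds, genes=genes, lnc_genes=lnc_genes,
                       te_intervals=te_intervals, track=track, cpg=cpg)


def _state_probability(cpg: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Per-CpG probability of the methylated state (feature + exon rank)."""
    w = cpg["feature"].map(config.w_high).to_numpy(float)
    exonic = (cpg["kind"].to_numpy() == "exon") & \
        cpg["feature"].isin(["CDS", "exon_UTR"]).to_numpy()
    ranks = np.clip(cpg["rank"].to_numpy(), 1, len(config.w_high_exon_rank)) - 1
    w = np.where(exonic, np.asarray(config.w_high_exon_rank)[ranks], w)
    return w


def simulate_methylomes(genome: GenomeTruth, config: SimConfig
                        ) -> tuple[MethTruth, list[SampleMethylome]]:
    """Draw per-site levels, DM shifts, and per-sample read counts.

    Levels follow the beta mixture (methylated state with probability
    w_high(feature, rank)); a fraction ``f_dm`` of methylated sites shifts by
    ``delta_dm`` points in population 2, hypomethylated with probability
    ``p_hypo``.  Coverage is negative-binomial and methylated read counts are
    beta-binomial with intra-site correlation ``sample_rho``.
    """
    config.validate()
    if len(genome.cpg) == 0:
        raise ValueError("genome has no CpGs")
    rng = np.random.default_rng(config.seed + 1)
    cpg = genome.cpg
    n = len(cpg)
    w = _state_probability(cpg, config)
    high = rng.random(n) < w
    level1 = np.where(high, rng.beta(*config.beta_high, size=n),
                      rng.beta(*config.beta_low, size=n))
    dm = high & (rng.random(n) < config.f_dm)
    hypo = dm & (rng.random(n) < config.p_hypo)
    hyper = dm & ~hypo
    delta = config.delta_dm / 100.0
    level2 = level1.copy()
    level2[hypo] = np.maximum(level1[hypo] - delta, 0.0)
    # keep a guaranteed positive shift for hyper sites near the ceiling
    level1[hyper] = np.minimum(level1[hyper], 1.0 - delta)
    level2[hyper] = level1[hyper] + delta
    direction = np.full(n, "", dtype=object)
    direction[hypo] = "hypo"
    direction[hyper] = "hyper"
    truth = cpg[["scaffold", "position", "strand"]].copy()
    truth["level_pop1"] = level1
    truth["level_pop2"] = level2
    truth["dm_flag"] = dm
    truth["dm_direction"] = direction
    truth["state_high"] = high

    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)
    samples = []
    for pop_i, pop in enumerate(config.pop_names):
        level = level1 if pop_i == 0 else level2
        lv = np.clip(level, 1e-9, 1.0 - 1e-9)
        for s in range(config.n_samples_per_pop):
            cov = rng.negative_binomial(k, p_nb, size=n)
            if config.sample_rho < 1e-9:
                p_site = lv
            else:
                lam = (1.0 - config.sample_rho) / config.sample_rho
                p_site = rng.beta(lv * lam, (1.0 - lv) * lam)
            meth = rng.binomial(cov, p_site)
            rec = cpg[["scaffold", "position", "strand"]].copy()
            rec["coverage"] = cov
            rec["count_meth"] = meth
            rec["count_unmeth"] = cov - meth
            samples.append(SampleMethylome(sample_id=f"{pop}{s + 1}",
                                           population=pop,
                                           records=rec[RECORD_COLUMNS]))
    return MethTruth(sites=truth), samples


def simulate_spikein(config: SimConfig) -> SampleMethylome:
    """Unmethylated control methylome at the configured conversion rate."""
    rng = np.random.default_rng(config.seed + 7)
    n = config.spikein_sites
    pos = np.sort(rng.choice(np.arange(1, 48_502), size=n, replace=False))
    k = config.coverage_dispersion
    cov = rng.negative_binomial(k, k / (k + config.coverage_mean), size=n)
    meth = rng.binomial(cov, 1.0 - config.conversion_rate)
    rec = pd.DataFrame({"scaffold": "lambda_control", "position": pos,
                        "strand": "F", "coverage": cov, "count_meth": meth,
                        "count_unmeth": cov - meth})
    return SampleMethylome("lambda_spikein", "control", rec)


def window_theta(genome: GenomeTruth, meth_truth: MethTruth | None,
                 config: SimConfig) -> pd.DataFrame:
    """Per-window theta = theta_base * exp(slope * meth_density).

    meth_density is the fraction of the window's CpGs in the methylated
    state (0 for CpG-less windows or when no methylation truth is supplied).
    """
    windows = window_grid(genome.scaffolds, config.window_size)
    dens = np.zeros(len(windows))
    if meth_truth is not None:
        wi = assign_windows(meth_truth.sites["scaffold"].to_numpy(),
                            meth_truth.sites["position"].to_numpy(), windows)
        inside = wi >= 0
        n_cpg = np.bincount(wi[inside], minlength=len(windows)).astype(float)
        n_high = np.bincount(wi[inside],
                             weights=meth_truth.sites["state_high"].to_numpy()[inside],
                             minlength=len(windows))
        with np.errstate(invalid="ignore", divide="ignore"):
            dens = np.where(n_cpg > 0, n_high / n_cpg, 0.0)
    out = windows.copy()
    out["meth_density"] = dens
    out["theta"] = config.theta_base * np.exp(config.theta_meth_slope * dens)
    return out


def simulate_variants(genome: GenomeTruth, config: SimConfig,
                      meth_truth: MethTruth | None = None) -> PopTruth:
    """Draw SNPs under Balding-Nichols structure with the theta coupling.

    SNP positions land in windows with probability proportional to window
    theta; a fraction ``p_snp_at_cpg`` is placed exactly on CpG positions and
    flagged C>T.  Population frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F)
    around a Uniform(0.05, 0.95) ancestral frequency; genotypes are HWE
    binomial draws within population.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    theta_df = window_theta(genome, meth_truth, config)
    n_snps = config.n_snps
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    n_at_cpg = int(round(n_snps * config.p_snp_at_cpg))
    cpg_pos = genome.cpg[["scaffold", "position"]]
    if n_at_cpg > len(cpg_pos):
        raise SizingError(f"{n_at_cpg} CpG-overlap SNPs requested but only "
                          f"{len(cpg_pos)} CpGs exist")

    # window weights proportional to theta
    wts = theta_df["theta"].to_numpy()
    wts = wts / wts.sum()

    # CpG SNPs: weight CpGs by their window's theta
    cpg_wi = assign_windows(cpg_pos["scaffold"].to_numpy(),
                            cpg_pos["position"].to_numpy(), theta_df)
    cpg_w = np.where(cpg_wi >= 0, theta_df["theta"].to_numpy()[np.clip(cpg_wi, 0, None)],
                     config.theta_base)
    rows = []
    if n_at_cpg > 0:
        pick = rng.choice(len(cpg_pos), size=n_at_cpg, replace=False,
                          p=cpg_w / cpg_w.sum())
        for i in pick:
            rows.append((cpg_pos["scaffold"].iat[i], int(cpg_pos["position"].iat[i]),
                         "C", "T", True))
    # non-CpG SNPs: window draw then uniform position, rejecting CpG collisions
    taken = {(r[0], r[1]) for r in rows}
    cpg_set = set(zip(cpg_pos["scaffold"], cpg_pos["position"]))
    n_other = n_snps - n_at_cpg
    if n_other > 0:
        win_idx = rng.choice(len(theta_df), size=n_other, p=wts)
        bases = "ACGT"
        for wi_ in win_idx:
            row = theta_df.iloc[wi_]
            for _ in range(100):
                pos = int(rng.integers(row["start"], row["end"] + 1))
                key = (row["scaffold"], pos)
                if key not in taken and key not in cpg_set:
                    break
            taken.add(key)
            ref = bases[rng.integers(4)]
            alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
            rows.append((key[0], key[1], ref, alt, False))
    snps = pd.DataFrame(rows, columns=["scaffold", "position", "ref", "alt", "at_cpg"])
    snps = snps.sort_values(["scaffold", "position"]).reset_index(drop=True)

    m = len(snps)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    F = config.fst_truth
    if F == 0:
        p1, p2 = p_anc.copy(), p_anc.copy()
    else:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    snps["p_anc"] = p_anc
    snps["p_pop1"] = p1
    snps["p_pop2"] = p2

    n_ind = config.n_indiv_per_pop
    g1 = rng.binomial(2, p1[None, :].repeat(n_ind, axis=0))
    g2 = rng.binomial(2, p2[None, :].repeat(n_ind, axis=0))
    geno = np.vstack([g1, g2]).astype(np.int8)
    pops = ([config.pop_names[0]] * n_ind) + ([config.pop_names[1]] * n_ind)
    ids = [f"{p}_ind{i % n_ind + 1}" for i, p in enumerate(pops)]
    gm = GenotypeMatrix(genotypes=geno, scaffolds=snps["scaffold"].to_numpy(),
                        positions=snps["position"].to_numpy(int),
                        individuals=ids, populations=pops)
    return PopTruth(snps=snps, genotypes=gm, window_theta=theta_df)


# --- fixture writing -------------------------------------------------------

def _write_gff3(genome: GenomeTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in genome.scaffolds.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in genome.genes + genome.lnc_genes:
            lnc = g.biotype == "lncRNA"
            fh.write(f"{g.scaffold}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t."
                     f"\tID={g.gene_id};gene_biotype="
                     f"{'lncRNA' if lnc else 'protein_coding'}\n")
            for tx in g.transcripts:
                kind = "lnc_RNA" if lnc else "mRNA"
                fh.write(f"{g.scaffold}\tsim\t{kind}\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t.\tID={tx.tx_id};Parent={g.gene_id}\n")
                for i, (s, e) in enumerate(sorted(tx.exons)):
                    fh.write(f"{g.scaffold}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t."
                             f"\tID={tx.tx_id}.e{i + 1};Parent={tx.tx_id}\n")
                for i, (s, e) in enumerate(sorted(tx.cds)):
                    fh.write(f"{g.scaffold}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0"
                             f"\tID={tx.tx_id}.c{i + 1};Parent={tx.tx_id}\n")
        for i, (scaffold, s, e) in enumerate(genome.te_intervals):
            fh.write(f"{scaffold}\tsim\ttransposable_element\t{s}\t{e}\t.\t+\t."
                     f"\tID=te_{i + 1}\n")


def _write_vcf(pop_truth: PopTruth, genome: GenomeTruth, path: str) -> None:
    gm = pop_truth.genotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in genome.scaffolds.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individuals) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for j, row in pop_truth.snps.iterrows():
            gts = "\t".join(gt_map[int(g)] for g in gm.genotypes[:, j])
            fh.write(f"{row['scaffold']}\t{row['position']}\t.\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def write_fixture_set(genome: GenomeTruth, meth_truth: MethTruth,
                      samples: list[SampleMethylome], pop_truth: PopTruth,
                      config: SimConfig, directory: str,
                      spikein: SampleMethylome | None = None) -> dict:
    """Emit GFF3, methylKit call files, VCF, genotype and truth tables.

    Returns the manifest (also written as JSON) recording the seed, config
    and file list; regeneration with the same config is byte-identical.
    """
    os.makedirs(directory, exist_ok=True)
    files = {}

    path = os.path.join(directory, "annotation.gff3")
    _write_gff3(genome, path)
    files["gff3"] = "annotation.gff3"

    with open(os.path.join(directory, "scaffold_lengths.tsv"), "w") as fh:
        for name, length in genome.scaffolds.items():
            fh.write(f"{name}\t{length}\n")
    files["scaffold_lengths"] = "scaffold_lengths.tsv"

    files["calls"] = []
    for m in samples:
        fname = f"{m.sample_id}.methylkit.txt"
        write_methylkit_file(m, os.path.join(directory, fname))
        files["calls"].append(fname)
    if spikein is not None:
        write_methylkit_file(spikein, os.path.join(directory, "spikein.methylkit.txt"))
        files["spikein"] = "spikein.methylkit.txt"

    _write_vcf(pop_truth, genome, os.path.join(directory, "snps.vcf"))
    files["vcf"] = "snps.vcf"

    gm = pop_truth.genotypes
    geno_df = pd.DataFrame({"scaffold": gm.scaffolds, "position": gm.positions})
    for i, (pop, iid) in enumerate(zip(gm.populations, gm.individuals)):
        geno_df[f"{pop}:{iid}"] = gm.genotypes[i]
    geno_df.to_csv(os.path.join(directory, "genotypes.tsv"), sep="\t", index=False)
    files["genotypes"] = "genotypes.tsv"

    meth_truth.sites.to_csv(os.path.join(directory, "truth_methylation.tsv"),
                            sep="\t", index=False)
    pop_truth.snps.to_csv(os.path.join(directory, "truth_snps.tsv"),
                          sep="\t", index=False)
    pop_truth.window_theta.to_csv(os.path.join(directory, "truth_window_theta.tsv"),
                                  sep="\t", index=False)
    genome.cpg.to_csv(os.path.join(directory, "truth_cpg.tsv"), sep="\t", index=False)
    files["truth"] = ["truth_methylation.tsv", "truth_snps.tsv",
                      "truth_window_theta.tsv", "truth_cpg.tsv"]

    cfg = asdict(config)
    cfg["w_high_exon_rank"] = list(cfg["w_high_exon_rank"])
    cfg["pop_names"] = list(cfg["pop_names"])
    cfg["beta_high"] = list(cfg["beta_high"])
    cfg["beta_low"] = list(cfg["beta_low"])
    manifest = {"seed": config.seed, "config": cfg, "files": files,
                "n_samples": len(samples), "n_cpgs": int(len(genome.cpg)),
                "n_snps": int(len(pop_truth.snps))}
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def simulate_all(config: SimConfig):
    """Genome, methylomes, spike-in and variants from one config."""
    genome = simulate_genome(config)
    meth_truth, samples = simulate_methylomes(genome, config)
    pop_truth = simulate_variants(genome, config, meth_truth)
    spikein = simulate_spikein(config)
    return genome, meth_truth, samples, pop_truth, spikein
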