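# Methods

This note documents the models, conventions and numerical choices behind
`methylpop`, in the order data flows through the pipeline.

## Input model and filtering cascade

Methylation calls arrive per cytosine in the 7-column methylKit text dialect.
Counts are the canonical store: `count_meth = round(coverage * freqC / 100)`
is reconstructed once at parse time and all percentages are derived views, so
rounding cannot drift through the cascade. F and R cytosines of a CpG are
kept as distinct records (no destranding).

The cascade is: per-sample coverage filter (drop `< 10×`; drop above the
per-sample 99th coverage percentile), median coverage normalization, strict
intersection ("unite") of site keys across samples re-checking `>= 10×`
after rounding, and SNP-overlap masking. Choices:

- **Percentile definition**: nearest-rank on the sample's own empirical
  coverage vector — the value at index `ceil(p/100 · n)` of the sorted
  vector. Reproducible and exact; computed per sample, not pooled.
- **Median normalization**: `factor_s = median(sample medians)/median_s`;
  coverage and methylated counts are re-rounded so per-site %methylation is
  preserved to within `100/coverage` of its pre-normalization value.
- **SNP masking** matches on (scaffold, position) for any biallelic SNP — a
  conservative superset of C>T-only masking (`ct_only=True` restricts to
  C>T/G>A).
- **Conversion QC** on an unmethylated spike-in reports the raw conversion
  rate `100·Σ count_unmeth / Σ coverage` and the fraction of sites at or
  above a liberal 10% call threshold.

Every stage emits a `FilterReport` whose counts must conserve
(`input = removed + retained`); this is asserted in code, not just tested.

## Site classes and genomic context

Per-site mean %methylation across samples is classified unmethylated
`[0,10)`, sparse `[10,50)`, high `[50,100]`. The half-open boundaries are a
deliberate resolution of the ambiguity between "≤10%/≥50%" and "<10%/>50%"
conventions: exactly 50% is "high", exactly 10% is "sparse"; both bounds are
configurable.

The feature track assigns every position exactly one class by precedence
`CDS > exon_UTR > intron > lncRNA > TE > upstream_flank > downstream_flank >
intergenic`. Coding features dominate so that mutually exclusive percentages
sum to 100. Flanks default to 1000 bp on each side of the gene span
(strand-aware); the flank length is a free parameter since no standard value
exists. Exon/intron ranks are numbered 1..k in transcription direction on
the longest isoform per gene (maximal summed exon length; ties broken by
lexicographically smallest transcript ID). Rank profiles report both raw
class counts and the "relative" percentage — class count over all CpGs at
that rank — which is the scale on which the exon 2–4 methylation peak is
visible.

TSS distances are signed: positive downstream of the owning gene's
transcription direction, zero counted as downstream; nearest TSS by absolute
genomic distance with ties resolved toward the lower scaffold coordinate and
flagged. Both absolute and signed means are reported, since "mean distance"
is ambiguous between the two.

Feature enrichment uses the Yates continuity-corrected χ² (df=1) on 2×2
tables of (in-feature vs not) × (target class vs all CpGs), BH-corrected
across the eight features; expected cells < 1 are flagged on the result
rather than fatal.

## Differential methylation

Sites are pre-filtered on variability: the across-sample SD (n−1 formula) of
%methylation must strictly exceed 2 percentage points. Invariant sites are
uninformative for a two-group contrast and only inflate the multiple-testing
burden.

The test pools methylated/unmethylated counts per population into a 2×2
table and computes the Pearson χ² (df=1; no continuity correction — Yates is
reserved for the feature-enrichment test). Overdispersion is estimated from
per-sample Pearson residuals against the pooled group proportions,

    φ̂ = Σ_s r_s² / (S − 2),   r_s = (m_s − c_s p̂_g) / sqrt(c_s p̂_g (1 − p̂_g)),

the quasi-likelihood scale with S−2 degrees of freedom (two estimated
proportions). The statistic is divided by φ̂ only when a dispersion screen —
a χ²_{S−2} test of the residual sum at α = 0.05 — indicates φ̂ > 1 is real.
Unconditional scaling by `max(1, φ̂)` makes a binomial-null test noticeably
conservative (random φ̂ > 1 draws deflate by chance; measured rejection
0.037 instead of 0.05 at 20k null sites), while test-then-correct keeps the
nominal level on binomial data (0.047) and still shrinks the rejection rate
from 0.64 to 0.11 under strong beta-binomial overdispersion (ρ = 0.2).
Under the generator's default ρ = 0.05 with ~75× coverage the scale is
φ ≈ 1 + (c−1)ρ ≈ 4.7, which genuinely limits power for 20-point shifts —
a property of the correction, not a defect.

Edge conventions: a site where either group has zero total coverage is
flagged and skipped; pooled proportions of 0 or 1 in both groups give p = 1.
Calls require q ≤ 0.01 (BH step-up) and |Δ| ≥ 10 points; direction is
relative to a *named* focal population (a required keyword, preventing
silent sign flips when the population order changes).

Sample-structure views: PCA on the site-centered %methylation matrix (SVD);
hierarchical clustering on 1 − Pearson correlation distances with the
Ward.D2 update (scipy's `ward` on a precomputed condensed distance matrix).
A zero-variance sample profile makes correlation undefined and raises an
error naming the sample.

## Population genetics

Estimators are genotype-based (0/1/2 dosages with missing values), not
genotype-likelihood-based: per-site π = 2j(n−j)/(n(n−1)) over n non-missing
alleles; Hudson F_ST components per site, combined as ratio of sums within
1-kb windows and genome-wide. Numeric identity with likelihood-based tools
is not expected; the estimators are validated against their own generating
model instead (Balding–Nichols recovery of F = 0.025 ± 0.01 at 10⁴ sites).

Windows are a fixed non-overlapping grid anchored at position 1, width =
step = 1000 bp, inclusive coordinates; trailing partial windows are dropped
so every window has a full-width denominator. Window π divides the summed
variant-site π by the *callable* positions of the window (all, unless a mask
says otherwise) — monomorphic positions count in the denominator. Bootstrap
CIs are percentile intervals over window blocks (default 1000 replicates,
seeded); for F_ST the resampled statistic is the ratio of summed components,
not a mean of ratios.

Genotype PCA mean-imputes missing entries per site, centers by 2p̂ and (by
default) scales by sqrt(2p̂(1−p̂)).

## Window integration

The window table joins, per complete 1-kb window with ≥ 1 CpG: CpG count,
mean %methylation per CpG, highly methylated count `n_high` and proportion,
mean |pooled %methylation difference| per CpG, π and F_ST. π is floored at
ε = 1e−6 before log-transforming (windows with π = 0 exist; the floor keeps
log π finite without perturbing observed values).

Two zero-inflated models relate methylation load to diversity:

- **ZINB**: counts `n_high` with NB2 kernel (variance μ + μ²/θ),
  log μ = β0 + β1·log π, constant zero-inflation mass π0. Fit by maximum
  likelihood via statsmodels' zero-inflated NB; θ is reported as 1/α.
- **ZIBB**: proportions `n_high/n_cpgs` with beta-binomial kernel, logit
  mean link, intra-class correlation ρ with shapes
  (μ(1−ρ)/ρ, (1−μ)(1−ρ)/ρ), constant π0 on y = 0. No installed
  implementation exists, so the likelihood is maximized directly
  (Nelder–Mead from method-of-moments multi-starts; Hessian-based SEs).
  Below ρ = 1e−7 the beta-binomial pmf is evaluated in its exact binomial
  limit — the γ-function differences otherwise lose precision when the
  shapes reach ~1/ρ.

Non-convergent or degenerate fits (e.g. all-zero response) return flagged
fit objects rather than raising, so driver scripts can report them.

The "windows with methylation" view keeps windows containing at least one
CpG at ≥ 10% mean methylation, mirroring the exclusion used when asking
whether differentiation tracks methylation differences once never-methylated
regions are removed.

## Synthetic data generator

The generator emulates the structure this analysis assumes for a sparse
insect methylome, with every latent quantity recorded as recoverable truth.
Defaults are the study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| scaffolds | 6 × 150 kb | desk-scale genome (0.9 Mb) |
| genes / lncRNAs / TEs | 42 / 6 / 12 | length-proportional placement, random strands |
| intron length mean | 1500 bp | makes intron+intergenic carry ~3/4 of CpGs, intron-leading |
| CpG density | 0.015–0.03 /bp by feature | CDS-enriched |
| state weights w_high | CDS 0.09; introns 0.0017; intergenic 0.0004; exon ranks (0.014, 0.101, 0.126, 0.102, then decay) | exon 2–4 peak, first exon low |
| levels | Beta(8,2) methylated, Beta(0.5,100) background | bimodal; global mean ≈ 1.1% |
| samples | 4 + 4 WGBS | two populations (CA low-, OR high-elevation) |
| coverage | NB, mean 75, size 10 | ≈ 75× depth |
| sample_rho | 0.05 | beta-binomial intra-site correlation, so the overdispersion correction is exercised |
| f_dm / delta_dm / p_hypo | 0.3 / 20 pp / 0.876 | DM truth among methylated-state sites; hypomethylation bias in OR |
| SNPs | 5000; 4% exactly on CpGs as C>T | masking overlap realistic |
| structure | Balding–Nichols F = 0.025, 8+8 individuals, HWE within population | weak differentiation |
| coupling | θ(window) = 0.002·exp(−3.0·meth_density) | negative π–methylation relation |

Calibration notes (all fixed before the acceptance machinery existed):
the background beta (0.5, 100) and the gene/intron geometry were set so the
realized global methylation (~1.1%), the highly methylated fraction
(~0.78%), and the feature composition match the published profile of a
bumble-bee methylome; `f_dm = 0.3` is a *truth* fraction chosen so a
desk-scale genome carries a few hundred DM sites, enough for the 87.6%
hypomethylation bias to be statistically recoverable (observed DM calls in a
real study are not an estimate of the truth fraction); the coupling slope
−3.0 puts the realized window correlation in the regime of the published
relationship (r ≈ −0.1 at desk scale; the sparse desk genome bounds
attainable |r|).

SNP positions are drawn with probability proportional to window θ, which is
how the methylation–diversity coupling enters; population frequencies are
Beta(p(1−F)/F, (1−p)(1−F)/F) draws around a Uniform(0.05, 0.95) ancestral
frequency, and F = 0 degenerates exactly to the ancestral frequency.

What the generator does *not* model: read-level artifacts (FASTQ,
sequencing error, mapping), non-CpG contexts, linkage disequilibrium between
SNPs, colony/relatedness structure within populations (samples are
independent draws), and spatially clustered methylation domains beyond the
gene-body structure. Passing tests therefore demonstrate correctness of the
estimators and the recoverability of the built-in structure — not robustness
to alignment artifacts or cryptic relatedness in real data.

## Problem sizes

The default fixture is 0.9 Mb / ~16.5k CpGs / 8 samples and runs the full
pipeline in ~2 s; the acceptance script scales to 12 scaffolds of 150–450 kb
(3.6 Mb, ~60k CpGs, 20k SNPs, 3.6k windows), chosen so every reported
quantity has enough sites/windows behind it to be stable while the whole
recomputation stays under a minute. Statistical suites use dedicated sizes:
20k-site null for test calibration, 10⁴ SNPs for F_ST recovery, 2000 windows
for ZINB/ZIBB recovery, and 100 seeded replicates (4-scaffold genomes) for
coupling sign recovery.

## Known limitations

- The overdispersion estimator is an explicit, tested interpretation of
  "basic overdispersion correction"; bit-compatibility with any particular
  R implementation is not claimed.
- Window π requires a callable-sites denominator; without one, only
  per-variant-site π is meaningful (the generator provides full
  callability).
- The hyper-direction DM shift caps truth levels at 1 − Δ, slightly
  compressing the level distribution of hypermethylated truth sites.
- `exon_intron_rank_breakdown` assigns sites in overlapping genes to the
  first containing ranked interval; overlapping gene models are rare in the
  generator but real annotations may need a priority rule.
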