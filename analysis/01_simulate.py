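#!/usr/bin/env python
"""Generate the synthetic study fixture set.

Writes a desk-scale bumble-bee-style methylome study to results/fixtures/:
six scaffolds with gene models (GFF3), eight WGBS call files (4 low-elevation
CA, 4 high-elevation OR), an unmethylated spike-in control, a SNP VCF, a
genotype table for 8+8 resequenced individuals, and the ground-truth tables
every later stage is checked against.
"""

import json
import sys

from methylpop import pipeline as pl
from methylpop.synthetic_data import SimConfig

OUTDIR = "results/fixtures"


def main(seed: int = 1) -> None:
    cfg = SimConfig(seed=seed)
    manifest = pl.run_simulate(cfg, OUTDIR)
    print(f"wrote fixture set to {OUTDIR}")
    print(f"  scaffolds : {cfg.n_scaffolds} x {cfg.scaffold_length:,} bp")
    print(f"  CpGs      : {manifest['n_cpgs']:,}")
    print(f"  samples   : {manifest['n_samples']} WGBS "
          f"({cfg.n_samples_per_pop} per population)")
    print(f"  SNPs      : {manifest['n_snps']:,} "
          f"(Balding-Nichols F = {cfg.fst_truth})")
    print(f"  manifest  : {OUTDIR}/manifest.json (seed {manifest['seed']})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
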