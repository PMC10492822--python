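#!/usr/bin/env python
"""Population differential methylation.

Filters low-variability CpGs (SD > 2 across samples), tests each retained
site with the overdispersion-corrected chi-square, applies BH FDR, and calls
sites with >= 10 percentage-point difference at q <= 0.01 as hypo- or
hypermethylated in the high-elevation (OR) population.  Also writes the
sample-structure views (PCA, Ward.D2 clustering) and the per-scaffold DM
density.  Tables land in results/diffmeth/.
"""

import json
import os

import numpy as np

from methylpop import differential_methylation as dm
from methylpop import pipeline as pl

FIXTURES = "results/fixtures"
OUTDIR = "results/diffmeth"


def main() -> None:
    data = pl.load_fixture_dir(FIXTURES)
    cfg = pl.PipelineConfig(focal_pop="OR")
    matrix, _ = pl.build_united(data["samples"], data["snps"], cfg)
    res = pl.run_diffmeth(matrix, "CA", "OR", cfg)
    os.makedirs(OUTDIR, exist_ok=True)
    res["calls"].to_csv(f"{OUTDIR}/dm_results.tsv", sep="\t", index=False)
    sig = res["calls"][res["calls"]["significant"]]
    sig.to_csv(f"{OUTDIR}/dm_significant.tsv", sep="\t", index=False)

    vf = res["variability"]
    print(f"variability filter: {vf.n_retained:,} of {vf.n_input:,} CpGs kept "
          f"({vf.pct_excluded:.2f}% excluded as SD <= {vf.sd_min})")
    s = res["summary"]
    print(f"differentially methylated sites: {s['n_significant']} "
          f"({s['n_hypo']} hypo / {s['n_hyper']} hyper in OR"
          + (f"; {s['hypo_pct']:.1f}% hypomethylated)" if s["n_significant"]
         else ")"))
    var_pct = 100 * res["pca_varfrac"][:2]
    print(f"PCA of variable CpGs: PC1+PC2 explain {var_pct.sum():.1f}% "
          f"of variance")
    table, dens = dm.scaffold_dm_density(sig, data["scaffold_lengths"])
    table.to_csv(f"{OUTDIR}/dm_per_scaffold.tsv", sep="\t", index=False)
    if dens:
        print(f"DM count vs scaffold length: Pearson r = "
              f"{dens['pearson_r']:.2f} (p = {dens['pearson_p']:.3g})")
    with open(f"{OUTDIR}/summary.json", "w") as fh:
        json.dump({"summary": s, "pct_excluded": vf.pct_excluded,
                   "pca_var_pct": var_pct.tolist(),
                   "scaffold_density": dens}, fh, indent=2, default=float)
    print(f"tables -> {OUTDIR}/")


if __name__ == "__main__":
    main()
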