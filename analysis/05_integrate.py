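#!/usr/bin/env python
"""Methylation-diversity integration on the 1-kb grid.

Joins per-window methylation summaries (CpG counts, highly methylated
counts/proportions, inter-population differences) with pi and F_ST, computes
the correlation panel, and fits the zero-inflated negative-binomial and
zero-inflated beta-binomial regressions of methylated-CpG load on log pi.
Tables land in results/integration/.
"""

import dataclasses
import json
import os

from methylpop import pipeline as pl

FIXTURES = "results/fixtures"
OUTDIR = "results/integration"


def main() -> None:
    data = pl.load_fixture_dir(FIXTURES)
    cfg = pl.PipelineConfig(seed=1, focal_pop="OR")
    char = pl.run_characterize(data["samples"], data["genes"],
                               data["lnc_genes"], data["te_intervals"],
                               data["snps"], data["scaffold_lengths"], cfg)
    dmres = pl.run_diffmeth(char["matrix"], "CA", "OR", cfg)
    pgres = pl.run_popgen(data["genotypes"], data["scaffold_lengths"],
                          "CA", "OR", cfg)
    res = pl.run_integrate(char, dmres["calls"], pgres,
                           data["scaffold_lengths"], cfg)
    os.makedirs(OUTDIR, exist_ok=True)
    res["table"].to_csv(f"{OUTDIR}/window_table.tsv", sep="\t", index=False)

    print(f"window table: {len(res['table']):,} complete 1-kb windows "
          f"with >= 1 CpG")
    for name, c in res["correlations"].items():
        print(f"  {name}: r = {c['pearson_r']:.3f} "
              f"(t = {c['pearson_t']:.1f}), rho = {c['spearman_rho']:.3f}")
    if res["fst_vs_absdiff_excl"] is not None:
        c = res["fst_vs_absdiff_excl"]
        print(f"  fst_vs_absdiff, methylated windows only (n = {c['n']}): "
              f"r = {c['pearson_r']:.3f}")
    zinb, zibb = res["zinb"], res["zibb"]
    print(f"ZINB:  n_high ~ log pi slope = {zinb.beta1:.3f} "
          f"(SE {zinb.se.get('beta1', float('nan')):.3f}, theta = "
          f"{zinb.theta:.2f}, pi0 = {zinb.pi0:.2f}, converged = {zinb.converged})")
    print(f"ZIBB:  prop_high ~ log pi slope = {zibb.beta1:.3f} "
          f"(rho = {zibb.rho:.3f}, pi0 = {zibb.pi0:.2f}, "
          f"converged = {zibb.converged})")
    with open(f"{OUTDIR}/summary.json", "w") as fh:
        json.dump({"correlations": res["correlations"],
                   "fst_vs_absdiff_excl": res["fst_vs_absdiff_excl"],
                   "zinb": dataclasses.asdict(zinb),
                   "zibb": dataclasses.asdict(zibb)}, fh, indent=2,
                  default=float)
    print(f"tables -> {OUTDIR}/")


if __name__ == "__main__":
    main()
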