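import numpy as np
import pandas as pd
import pytest

from methylpop import pipeline as pl
from methylpop.meth_io import SampleMethylome
from methylpop.site_filtering import UnitedMatrix
from methylpop.synthetic_data import SimConfig, simulate_all, write_fixture_set


@pytest.fixture(scope="session")
def sim_default():
    """One default-scale simulated study (genome, truth, 8 samples, variants)."""
    cfg = SimConfig(seed=7)
    genome, meth_truth, samples, pop_truth, spikein = simulate_all(cfg)
    return {"cfg": cfg, "genome": genome, "meth_truth": meth_truth,
            "samples": samples, "pop_truth": pop_truth, "spikein": spikein}


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_default):
    d = tmp_path_factory.mktemp("fixtures")
    write_fixture_set(sim_default["genome"], sim_default["meth_truth"],
                      sim_default["samples"], sim_default["pop_truth"],
                      sim_default["cfg"], str(d), spikein=sim_default["spikein"])
    return str(d)


@pytest.fixture(scope="session")
def char_default(sim_default):
    """Characterization results on the default simulated study."""
    g = sim_default["genome"]
    pt = sim_default["pop_truth"]
    snps = {(r.scaffold, r.position, r.ref, r.alt) for r in pt.snps.itertuples()}
    return pl.run_characterize(sim_default["samples"], g.genes, g.lnc_genes,
                               g.te_intervals, snps, g.scaffolds,
                               pl.PipelineConfig())


def make_methylome(rows, sample_id="s", population="P"):
    """rows: (scaffold, position, strand, coverage, meth)."""
    df = pd.DataFrame(rows, columns=["scaffold", "position", "strand",
                                     "coverage", "count_meth"])
    df["count_unmeth"] = df["coverage"] - df["count_meth"]
    return SampleMethylome(sample_id, population, df)


def make_matrix(coverage, meth, populations, scaffold="s1"):
    coverage = np.asarray(coverage)
    meth = np.asarray(meth)
    n = coverage.shape[0]
    sites = pd.DataFrame({"scaffold": scaffold,
                          "position": np.arange(1, n + 1), "strand": "F"})
    samples = [f"{p}{i}" for i, p in enumerate(populations)]
    return UnitedMatrix(sites, coverage, meth, samples, list(populations))
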