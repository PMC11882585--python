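import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methdiv.matrix import MethylationMatrix

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_matrix(sites, counts, groups):
    """Build a MethylationMatrix from literals.

    sites: list of (chrom, pos[, strand]); counts: per-sample mapping
    sample -> list of (meth, unmeth) aligned with sites; groups: sample ->
    group label.
    """
    rows = [(s[0], s[1], s[2] if len(s) > 2 else ".") for s in sites]
    site_df = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    order = np.lexsort((site_df["pos"], site_df["chrom"]))
    site_df = site_df.iloc[order].reset_index(drop=True)
    samples = list(counts)
    meth = np.array([[counts[s][i][0] for s in samples] for i in order])
    unmeth = np.array([[counts[s][i][1] for s in samples] for i in order])
    return MethylationMatrix(site_df, meth, unmeth, samples, dict(groups))


@pytest.fixture
def two_group_matrix():
    """4 sites x 4 samples, 2 per group, one strongly differential site."""
    sites = [("chr1", 100), ("chr1", 500), ("chr2", 50), ("chr2", 900)]
    counts = {
        "a1": [(18, 2), (10, 10), (0, 20), (15, 5)],
        "a2": [(17, 3), (11, 9), (1, 19), (14, 6)],
        "b1": [(2, 18), (9, 11), (0, 20), (15, 5)],
        "b2": [(3, 17), (10, 10), (1, 19), (16, 4)],
    }
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return make_matrix(sites, counts, groups)


@pytest.fixture(scope="session")
def small_truth():
    from methdiv.simulate import SimulationConfig, generate_truth

    cfg = SimulationConfig(
        seed=11, n_cpg=4000, n_planted_dmcs=150, n_snps=600,
        n_stretches=3, stretch_sites=6,
    )
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_truth):
    from methdiv.simulate import emit_files, sample_counts

    outdir = tmp_path_factory.mktemp("bundle")
    records = sample_counts(small_truth)
    paths = emit_files(records, small_truth, outdir)
    return paths
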