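import numpy as np
import pandas as pd
import pytest

from methdiv.io import ValidationError
from methdiv.reprogramming import (
    hierarchical_cluster,
    pool_replicates,
    stage_filter,
)

from conftest import make_matrix


def stage_matrix():
    """Two stages x two replicates over three sites."""
    sites = [("chr1", 10), ("chr1", 20), ("chr1", 30)]
    counts = {
        "r1": [(3, 7), (2, 8), (0, 0)],
        "r2": [(2, 8), (1, 4), (6, 0)],
        "r3": [(9, 1), (0, 5), (2, 2)],
        "r4": [(8, 2), (1, 9), (3, 3)],
    }
    groups = {"r1": "2C", "r2": "2C", "r3": "B", "r4": "B"}
    return make_matrix(sites, counts, groups)


class TestPoolReplicates:
    def test_counts_sum_within_stage(self):
        prof = pool_replicates(stage_matrix())
        assert prof.stages == ["2C", "B"]
        i = prof.sites.index[prof.sites["pos"] == 10][0]
        assert prof.meth[i, 0] == 5 and prof.unmeth[i, 0] == 15
        # fraction 5/20 = 0.25
        assert prof.fractions()[i, 0] == pytest.approx(0.25)

    def test_single_replicate_is_identity(self):
        m = make_matrix([("chr1", 10)], {"r1": [(3, 7)]}, {"r1": "S"})
        prof = pool_replicates(m)
        assert prof.meth[0, 0] == 3 and prof.unmeth[0, 0] == 7

    def test_absent_site_contributes_zero(self):
        prof = pool_replicates(stage_matrix())
        i = prof.sites.index[prof.sites["pos"] == 30][0]
        assert prof.meth[i, 0] == 6 and prof.unmeth[i, 0] == 0

    def test_missing_stage_assignment_rejected(self):
        m = stage_matrix()
        with pytest.raises(ValidationError):
            pool_replicates(m, {"r1": "2C"})


class TestStageFilter:
    def test_coverage_rule_per_stage(self):
        prof = pool_replicates(stage_matrix())
        all_sites = prof.sites
        # pooled coverages: pos10 (20,20), pos20 (15,15), pos30 (6,10)
        out5 = stage_filter(prof, all_sites, min_cov=5)
        assert len(out5) == 3
        out10 = stage_filter(prof, all_sites, min_cov=10)
        assert set(out10.index.get_level_values("pos")) == {10, 20}

    def test_site_selection(self):
        prof = pool_replicates(stage_matrix())
        dmcs = pd.DataFrame({"chrom": ["chr1"], "pos": [20]})
        out = stage_filter(prof, dmcs, min_cov=1)
        assert len(out) == 1 and out.index[0] == ("chr1", 20)

    def test_pool_then_filter_equals_filter_on_presummed(self):
        m = stage_matrix()
        prof = pool_replicates(m)
        presummed = make_matrix(
            [("chr1", 10), ("chr1", 20), ("chr1", 30)],
            {
                "2C": [(5, 15), (3, 12), (6, 0)],
                "B": [(17, 3), (1, 14), (5, 5)],
            },
            {"2C": "2C", "B": "B"},
        )
        prof2 = pool_replicates(presummed)
        a = stage_filter(prof, prof.sites, min_cov=5)
        b = stage_filter(prof2, prof2.sites, min_cov=5)
        pd.testing.assert_frame_equal(a, b)


class TestHierarchicalCluster:
    def test_identical_columns_merge_first(self):
        rng = np.random.default_rng(0)
        a = rng.random(50)
        df = pd.DataFrame({"A": a, "B": a, "C": 1 - a})
        res = hierarchical_cluster(df)
        # A and B are perfectly correlated: first merge joins leaves 0,1
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}
        assert res.newick.count("(") == 2

    def test_two_columns_trivial_tree(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"X": rng.random(20), "Y": rng.random(20)})
        res = hierarchical_cluster(df)
        assert res.leaf_order == ["X", "Y"]
        assert res.newick.startswith("(") and res.newick.endswith(";")

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"A": rng.random(30), "B": rng.random(30), "C": 0.5}
        )
        with pytest.warns(UserWarning, match="constant"):
            res = hierarchical_cluster(df)
        assert res.dropped == ["C"]
        assert set(res.labels) == {"A", "B"}

    def test_planted_blocks_recovered(self):
        """Stages sharing a methylation program cluster as sister pairs."""
        recovered = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base1 = rng.random(200)
            base2 = rng.random(200)
            df = pd.DataFrame(
                {
                    "s1": base1 + rng.normal(0, 0.05, 200),
                    "s2": base1 + rng.normal(0, 0.05, 200),
                    "s3": base2 + rng.normal(0, 0.05, 200),
                    "s4": base2 + rng.normal(0, 0.05, 200),
                }
            )
            res = hierarchical_cluster(df)
            first = set(res.linkage[0, :2].astype(int))
            second = set(res.linkage[1, :2].astype(int))
            if {0, 1} in (first, second) and {2, 3} in (first, second):
                recovered += 1
        assert recovered >= 9

    def test_invariant_to_site_order(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.random((100, 4)), columns=list("abcd"))
        res1 = hierarchical_cluster(df)
        res2 = hierarchical_cluster(df.sample(frac=1, random_state=0))
        assert res1.newick == res2.newick

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(pd.DataFrame({"A": [0.1, 0.9]}))


def test_simulated_stage_bundle_flows_through():
    """The generator's multi-stage mode (4 stages x 2 shallow replicates)
    feeds pooling, the 5X-in-all filter and clustering end to end."""
    from methdiv.simulate import (
        SimulationConfig,
        build_simulated_matrix,
        generate_truth,
    )

    cfg = SimulationConfig(
        seed=31, n_cpg=3000, group_labels=("2C", "CM", "B", "S"),
        samples_per_group=2, coverage_mean=6.0, coverage_dispersion=8.0,
        n_planted_dmcs=300, n_snps=200, n_stretches=0, stretch_sites=0,
        couple_fraction=0.0,
    )
    truth = generate_truth(cfg)
    m = build_simulated_matrix(truth)
    assert m.n_samples == 8 and len(m.group_labels) == 4
    profile = pool_replicates(m)
    assert profile.stages == sorted(cfg.group_labels)
    frac = stage_filter(profile, profile.sites, min_cov=5)
    # shallow coverage: the 5X-in-all-stages filter bites, but sites remain
    assert 0 < len(frac) < cfg.n_cpg
    res = hierarchical_cluster(frac)
    assert sorted(res.leaf_order) == sorted(cfg.group_labels)
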