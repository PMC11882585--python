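import filecmp

import numpy as np
import pandas as pd
import pytest

from methdiv.io import read_coverage_table, read_snp_table
from methdiv.proximity import nearest_distance_sites
from methdiv.simulate import (
    ConfigError,
    SimulationConfig,
    build_simulated_matrix,
    emit_files,
    generate_truth,
    sample_counts,
    simulate_bundle,
)


class TestGenerateTruth:
    def test_exact_planted_count(self):
        cfg = SimulationConfig(seed=2, n_cpg=10_000, n_planted_dmcs=200,
                               n_snps=500, n_stretches=3, stretch_sites=5)
        truth = generate_truth(cfg)
        assert int(truth.sites["is_planted_dmc"].sum()) == 200
        assert len(truth.sites) == 10_000

    def test_full_coupling_constraint(self):
        cfg = SimulationConfig(
            seed=3, n_cpg=3000, n_planted_dmcs=100, couple_fraction=1.0,
            d_couple=100, n_snps=400, n_stretches=0, stretch_sites=0,
        )
        truth = generate_truth(cfg)
        coupled = truth.sites[truth.sites["coupled"]]
        assert len(coupled) == 100
        assert (coupled["nearest_snp_bp"] <= 100).all()

    def test_delta_zero_leaves_groups_identical(self):
        cfg = SimulationConfig(seed=4, n_cpg=2000, n_planted_dmcs=50,
                               delta=0.0, n_snps=300, n_stretches=0,
                               stretch_sites=0)
        truth = generate_truth(cfg)
        assert np.allclose(truth.sites["p_H"], truth.sites["p_M"])

    def test_stretch_members_are_adjacent_dmcs(self):
        cfg = SimulationConfig(seed=5, n_cpg=4000, n_planted_dmcs=150,
                               n_snps=300, n_stretches=4, stretch_sites=6,
                               stretch_gap=(10, 200))
        truth = generate_truth(cfg)
        for sid, g in truth.sites[truth.sites["stretch_id"] >= 0].groupby(
            "stretch_id"
        ):
            assert len(g) == 6
            assert g["is_planted_dmc"].all()
            gaps = np.diff(np.sort(g["pos"].to_numpy()))
            assert (gaps <= 2000).all()

    def test_infeasible_config_rejected(self):
        with pytest.raises(ConfigError):
            generate_truth(SimulationConfig(n_cpg=100, n_planted_dmcs=200))
        with pytest.raises(ConfigError):
            generate_truth(
                SimulationConfig(n_planted_dmcs=50, n_stretches=10,
                                 stretch_sites=10)
            )

    def test_planted_roles_disjoint(self, small_truth):
        df = small_truth.sites
        in_stretch = df["stretch_id"] >= 0
        assert not (in_stretch & df["coupled"]).any()


class TestSampleCounts:
    def test_group_fractions_concentrate_on_truth(self, small_truth):
        """Pooled group fractions at strongly planted sites fall within 3
        binomial standard deviations of the configured means."""
        m = build_simulated_matrix(small_truth)
        key = pd.MultiIndex.from_frame(m.sites[["chrom", "pos"]])
        truth = small_truth.sites.set_index(["chrom", "pos"])
        ma, ua = m.pooled_counts("H")
        mb, ub = m.pooled_counts("M")
        pa = truth.loc[key, "p_H"].to_numpy()
        pb = truth.loc[key, "p_M"].to_numpy()
        for meth, tot, p in ((ma, ma + ua, pa), (mb, mb + ub, pb)):
            sd = np.sqrt(tot * p * (1 - p))
            resid = np.abs(meth - tot * p)
            assert (resid <= 4 * sd + 1e-9).mean() > 0.995

    def test_coverage_mean_within_five_percent(self, small_truth):
        m = build_simulated_matrix(small_truth)
        mean = m.coverage().mean()
        assert abs(mean - 30.0) / 30.0 < 0.05

    def test_methylation_is_bimodal(self, small_truth):
        """Dip between the low and high modes of the baseline mixture."""
        p = small_truth.sites["p_H"].to_numpy()
        low = ((p < 0.2)).mean()
        mid = ((p >= 0.4) & (p < 0.6)).mean()
        high = ((p >= 0.8)).mean()
        assert mid < low and mid < high

    def test_determinism(self, small_truth):
        a = sample_counts(small_truth)
        b = sample_counts(small_truth)
        for s in a:
            pd.testing.assert_frame_equal(a[s], b[s])


class TestEmitFiles:
    def test_manifest_contents(self, small_bundle, small_truth):
        cfg = small_truth.config
        n_cov = sum(1 for k in small_bundle if k.startswith("coverage:"))
        assert n_cov == 2 * cfg.samples_per_group
        for k in ("snps", "repeats", "sample_sheet", "truth"):
            assert small_bundle[k].exists()

    def test_bundle_round_trip(self, small_bundle, small_truth):
        """Re-reading an emitted coverage file reproduces the in-memory
        records (covered positions only)."""
        records = sample_counts(small_truth)
        sample = next(iter(records))
        emitted = read_coverage_table(small_bundle[f"coverage:{sample}"])
        df = records[sample]
        covered = df[(df["meth"] + df["unmeth"]) > 0].sort_values(
            ["chrom", "pos"]
        )
        assert len(emitted) == len(covered)
        got = [(r.chrom, r.pos, r.meth, r.unmeth) for r in emitted]
        want = list(
            zip(covered["chrom"], covered["pos"], covered["meth"],
                covered["unmeth"])
        )
        assert got == want

    def test_truth_snp_distances_recomputable(self, small_bundle, small_truth):
        snps = read_snp_table(small_bundle["snps"], min_af=0.10)
        recomputed = nearest_distance_sites(small_truth.sites, snps)
        assert np.array_equal(
            recomputed, small_truth.sites["nearest_snp_bp"].to_numpy()
        )

    def test_low_af_snps_filtered_on_read(self, small_bundle, small_truth):
        all_snps = read_snp_table(small_bundle["snps"], min_af=0.0)
        filtered = read_snp_table(small_bundle["snps"], min_af=0.10)
        assert len(filtered) < len(all_snps)

    def test_end_to_end_byte_determinism(self, tmp_path):
        cfg = SimulationConfig(seed=6, n_cpg=1500, n_planted_dmcs=60,
                               n_snps=200, n_stretches=2, stretch_sites=4)
        p1 = simulate_bundle(cfg, tmp_path / "a")
        p2 = simulate_bundle(cfg, tmp_path / "b")
        for k in p1:
            if k == "sample_sheet":
                continue  # embeds the output directory path
            assert filecmp.cmp(p1[k], p2[k], shallow=False), k
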