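"""Synthetic Pool-Seq generator: primitives, dataset structure, recovery."""

import numpy as np
import pandas as pd
import pytest

import poolscan as ps
from poolscan.pool_io import MISSING

from conftest import run_scan, superpool_pair


class TestDrawPopulationFreq:
    def test_zero_divergence_returns_ancestral_exactly(self, rng):
        assert ps.draw_population_freq(0.5, 0.0, rng) == 0.5
        vec = np.full(10, 0.31)
        assert np.array_equal(ps.draw_population_freq(vec, 0.0, rng), vec)

    def test_monte_carlo_mean_and_variance(self):
        rng = np.random.default_rng(123)
        draws = ps.draw_population_freq(np.full(100_000, 0.5), 0.1, rng)
        assert abs(draws.mean() - 0.5) < 0.01
        # Balding-Nichols variance is F p (1-p) = 0.025
        assert abs(draws.var() - 0.025) / 0.025 < 0.10

    @pytest.mark.parametrize("p, F", [(0.5, 1.0), (0.5, -0.1), (0.0, 0.1), (1.0, 0.1)])
    def test_parameter_errors(self, p, F, rng):
        with pytest.raises(ps.ContractError):
            ps.draw_population_freq(p, F, rng)


class TestSamplePoolCounts:
    def test_fixed_alleles(self, rng):
        assert ps.sample_pool_counts(1.0, 20, rng) == 20
        assert ps.sample_pool_counts(0.0, 20, rng) == 0

    def test_binomial_mean(self):
        rng = np.random.default_rng(7)
        draws = ps.sample_pool_counts(np.full(100_000, 0.5), 20, rng)
        assert abs(draws.mean() - 10.0) < 0.05
        assert draws.min() >= 0 and draws.max() <= 20

    def test_invalid_inputs(self, rng):
        with pytest.raises(ps.ContractError):
            ps.sample_pool_counts(1.2, 20, rng)
        with pytest.raises(ps.ContractError):
            ps.sample_pool_counts(0.5, 0, rng)


class TestConfigValidation:
    def test_island_outside_lg_rejected(self):
        cfg = ps.SimConfig(seed=1, islands=[ps.IslandSpec("LG01", 1, 3_000_000, 0.15)])
        with pytest.raises(ps.ContractError):
            cfg.validate()

    def test_overlapping_islands_rejected(self):
        cfg = ps.SimConfig(
            seed=1,
            islands=[
                ps.IslandSpec("LG01", 100_000, 300_000, 0.15),
                ps.IslandSpec("LG01", 250_000, 500_000, 0.15),
            ],
        )
        with pytest.raises(ps.ContractError):
            cfg.validate()

    def test_island_fst_must_exceed_background(self):
        cfg = ps.SimConfig(seed=1, islands=[ps.IslandSpec("LG01", 1, 1_000, 0.01)])
        with pytest.raises(ps.ContractError):
            cfg.validate()

    def test_every_pool_needs_a_superpool(self):
        cfg = ps.SimConfig(seed=1)
        cfg.superpool_map = {k: v for k, v in list(cfg.superpool_map.items())[:-1]}
        with pytest.raises(ps.ContractError):
            cfg.validate()


class TestSimulateDataset:
    def test_poisson_snp_count(self):
        cfg = ps.SimConfig(seed=3, lg_lengths={"LG01": 1_000_000}, snp_density=1e-3)
        m, _ = ps.simulate_dataset(cfg)
        assert abs(m.n_snps - 1000) <= 3 * np.sqrt(1000)

    def test_same_seed_bit_identical(self):
        cfg = ps.SimConfig(seed=42, lg_lengths={"LG01": 300_000})
        a, ta = ps.simulate_dataset(cfg)
        b, tb = ps.simulate_dataset(cfg)
        assert a == b
        pd.testing.assert_frame_equal(ta.snps, tb.snps)

    def test_counts_positions_and_truth_alignment(self, island_dataset, island_config):
        m, truth = island_dataset
        ploidy = np.array([p.ploidy for p in m.pools])
        present = m.counts != MISSING
        assert np.all(m.counts[present] >= 0)
        assert np.all((m.counts <= ploidy[None, :]) | ~present)
        assert len(truth.snps) == m.n_snps  # exactly one truth row per SNP
        for lg, grp in m.snps.groupby("lg"):
            assert grp["pos"].max() <= island_config.lg_lengths[lg]
            assert grp["pos"].is_monotonic_increasing

    def test_island_flags_agree_with_config(self, island_dataset, island_config):
        _, truth = island_dataset
        flagged = truth.snps["island_id"] != "."
        inside = np.zeros(len(truth.snps), dtype=bool)
        for isl in island_config.islands:
            inside |= (
                (truth.snps["lg"] == isl.lg)
                & (truth.snps["pos"] >= isl.start)
                & (truth.snps["pos"] <= isl.end)
            ).to_numpy()
        assert np.array_equal(flagged.to_numpy(), inside)

    def test_replicate_pools_concordant_without_divergence(self):
        cfg = ps.SimConfig(
            seed=5, lg_lengths={"LG01": 2_000_000, "LG02": 2_000_000},
            snp_density=5e-3, background_fst=0.0, missing_fraction=0.0,
        )
        m, _ = ps.simulate_dataset(cfg)
        freqs = m.frequencies()
        ia, ib = m.pool_index("wash_a"), m.pool_index("wash_b")
        assert m.n_snps >= 10_000
        res = ps.lin_ccc(freqs[:, ia], freqs[:, ib])
        assert res.rho_c > 0.9


class TestDivergenceCalibration:
    def test_floor_maps_to_zero(self):
        assert ps.calibrate_bn_divergence(0.0, 20, 6, 3) == 0.0
        assert ps.calibrate_bn_divergence(0.006, 20, 6, 3) == 0.0

    def test_monotone_in_target(self):
        vals = [ps.calibrate_bn_divergence(f, 20, 6, 3) for f in (0.02, 0.05, 0.15)]
        assert vals == sorted(vals) and vals[0] > 0

    def test_measured_background_fst_near_dial(self, island_scan, island_config):
        """Mean per-SNP Nei F_ST between the simulated superpools over the
        background SNPs is within 20% (relative) of background_fst."""
        filtered, per_snp, _, truth = island_scan
        merged = per_snp.merge(truth.snps[["lg", "pos", "island_id"]], on=["lg", "pos"])
        bg = merged.loc[merged["island_id"] == ".", "fst"].dropna()
        assert len(bg) >= 8_000
        target = island_config.background_fst
        assert abs(bg.mean() - target) / target < 0.20

    def test_island_snps_exceed_background(self, island_scan):
        filtered, per_snp, _, truth = island_scan
        merged = per_snp.merge(truth.snps[["lg", "pos", "island_id"]], on=["lg", "pos"])
        bg = merged.loc[merged["island_id"] == ".", "fst"].dropna()
        isl = merged.loc[merged["island_id"] != ".", "fst"].dropna()
        assert isl.mean() > 2 * bg.mean()

    def test_replicates_tighter_than_populations(self):
        """Global pairwise F_ST: replicate pools below pools from populations
        diverged at the background level."""
        cfg = ps.SimConfig(seed=9, lg_lengths={"LG01": 2_000_000}, snp_density=5e-3)
        m, _ = ps.simulate_dataset(cfg)
        m = ps.filter_complete_biallelic_variant(m)
        fst = ps.pairwise_global_fst(m)
        assert fst.loc["perv_a", "perv_b"] < fst.loc["perv_a", "near"]
        assert fst.loc["wash_a", "wash_b"] < fst.loc["zhemchug", "adak"]


class TestYamlConfig:
    def test_round_trip_fields(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "seed: 13\n"
            "snp_density: 0.002\n"
            "background_fst: 0.03\n"
            "lg_lengths: {LG01: 500000}\n"
            "islands:\n"
            "  - {lg: LG01, start: 100000, end: 200000, fst: 0.2}\n"
            "pools:\n"
            "  - {pool_id: a1, population: EBS, mean_depth: 60}\n"
            "  - {pool_id: a2, population: EBS, mean_depth: 60}\n"
            "  - {pool_id: b1, population: AI, mean_depth: 60}\n"
            "replicate_groups:\n"
            "  - {pool_ids: [a1, a2], perturb_fst: 0.0}\n"
        )
        cfg = ps.config_from_yaml(path)
        assert cfg.seed == 13
        assert cfg.background_fst == 0.03
        assert cfg.islands[0].fst == 0.2
        assert cfg.superpool_map == {"a1": "EBS", "a2": "EBS", "b1": "AI"}
        m, truth = ps.simulate_dataset(cfg)
        assert m.n_pools == 3

    def test_seed_mandatory(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("snp_density: 0.001\n")
        with pytest.raises(ps.ContractError):
            ps.config_from_yaml(path)


class TestTruthTable:
    def test_written_table_columns(self, tmp_path, island_dataset):
        _, truth = island_dataset
        path = tmp_path / "truth.tsv"
        truth.write(path)
        back = pd.read_csv(path, sep="\t")
        assert {"snp_id", "lg", "pos", "ancestral_p", "island_id"} <= set(back.columns)
        assert len(back) == len(truth.snps)
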