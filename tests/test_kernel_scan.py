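"""Window geometry, Gaussian kernel weighting, and pooled diversity statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import poolscan as ps
from poolscan.kernel_scan import _kernel_mass


class TestWindowScheme:
    def test_span_is_six_sigma(self):
        scheme = ps.WindowScheme()
        assert scheme.half_span == 90_000
        assert scheme.span == 180_000

    @pytest.mark.parametrize(
        "length, expected",
        [
            (220_000, [90_000, 110_000, 130_000]),
            (180_000, [90_000]),
            (100_000, []),
        ],
    )
    def test_make_windows(self, length, expected):
        centers = ps.make_windows({"LG01": length}, ps.WindowScheme())["LG01"]
        assert centers.tolist() == expected

    def test_windows_never_span_linkage_groups(self):
        out = ps.make_windows({"a": 200_000, "b": 500_000}, ps.WindowScheme())
        for lg, centers in out.items():
            assert np.all(centers - 90_000 >= 0)
            assert np.all(centers + 90_000 <= {"a": 200_000, "b": 500_000}[lg])


class TestKernelWeight:
    @pytest.mark.parametrize(
        "offset, expected",
        [(0, 1.0), (30_000, 0.606531), (90_000, 0.011109)],
    )
    def test_gaussian_values(self, offset, expected):
        assert ps.kernel_weight(100_000 + offset, 100_000, 30_000) == pytest.approx(
            expected, abs=1e-6
        )

    def test_zero_beyond_three_sigma(self):
        assert ps.kernel_weight(190_001, 100_000, 30_000) == 0.0


class TestWeightedWindowFst:
    def test_single_snp_returns_its_value(self):
        assert ps.weighted_window_fst([0.07], [55_000], 90_000, 30_000) == pytest.approx(0.07)

    def test_two_snp_weighted_mean(self):
        # (0.1 + e^-0.5 * 0.2) / (1 + e^-0.5)
        val = ps.weighted_window_fst([0.1, 0.2], [90_000, 120_000], 90_000, 30_000)
        assert val == pytest.approx(0.1377541, abs=1e-6)

    def test_constant_inputs_are_fixed_points(self):
        pos = np.array([70_000, 90_000, 110_000])
        assert ps.weighted_window_fst([0.3, 0.3, 0.3], pos, 90_000, 30_000) == pytest.approx(0.3)

    def test_no_defined_snps_gives_nan(self):
        assert np.isnan(ps.weighted_window_fst([np.nan], [90_000], 90_000, 30_000))

    def test_weights_all_one_degenerates_to_mean(self):
        # every SNP at the center -> kernel weight exactly 1 -> arithmetic mean
        vals = [0.1, 0.4, 0.3]
        got = ps.weighted_window_fst(vals, [90_000] * 3, 90_000, 30_000)
        assert got == pytest.approx(np.mean(vals), abs=1e-15)


class TestWeightedWindowDxy:
    def test_no_snps_gives_zero(self):
        assert ps.weighted_window_dxy([], [], 90_000, 30_000) == 0.0

    def test_unit_sigma_per_bp_normalization(self):
        # W = 1 + 2(e^-0.5 + e^-2 + e^-4.5) = 2.505950
        val = ps.weighted_window_dxy([0.5], [10], 10, 1)
        assert val == pytest.approx(0.199525, abs=1e-6)

    def test_linearity(self, rng):
        pos = rng.integers(10_000, 170_000, size=12)
        vals = rng.uniform(0, 1, size=12)
        one = ps.weighted_window_dxy(vals, pos, 90_000, 30_000)
        two = ps.weighted_window_dxy(2 * vals, pos, 90_000, 30_000)
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestWindowPi:
    def test_monomorphic_zero(self):
        assert ps.window_pi([0, 20, 0], 20, 100) == 0.0

    @pytest.mark.parametrize(
        "j, C, n, expected",
        [(10, 20, 7, 0.075188), (1, 20, 1, 0.1)],
    )
    def test_single_site_values(self, j, C, n, expected):
        assert ps.window_pi([j], C, n) == pytest.approx(expected, abs=1e-6)

    def test_ploidy_below_two_rejected(self):
        with pytest.raises(ps.ContractError):
            ps.window_pi([1], 1, 10)


class TestWindowThetaW:
    def test_values(self):
        assert ps.window_theta_w(0, 20) == 0.0
        assert ps.window_theta_w(1, 20) == pytest.approx(0.281870, abs=1e-6)
        assert ps.window_theta_w(10, 2) == pytest.approx(10.0)

    def test_printed_formula_variant_sums_to_ploidy(self):
        # optional variant divides by H_C instead of H_{C-1}
        std = ps.window_theta_w(5, 20)
        alt = ps.window_theta_w(5, 20, theta_sum_upper="C")
        assert alt < std
        assert alt == pytest.approx(5 / sum(1 / i for i in range(1, 21)))


def tajima_d_oracle(pi_sum, S, n):
    """Direct transcription of the Tajima (1989) D statistic."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_zero_when_pi_equals_theta(self):
        theta = ps.window_theta_w(8, 20)
        assert ps.window_tajimas_d(theta, 8, 20) == pytest.approx(0.0, abs=1e-12)

    def test_reference_value(self):
        assert ps.window_tajimas_d(3.0, 16, 20) == pytest.approx(-1.2444, abs=1e-4)

    @pytest.mark.parametrize("pi_sum, S, C", [(3.0, 16, 20), (10.0, 25, 120), (0.5, 2, 40)])
    def test_matches_independent_oracle(self, pi_sum, S, C):
        assert ps.window_tajimas_d(pi_sum, S, C) == pytest.approx(
            tajima_d_oracle(pi_sum, S, C), abs=1e-12
        )

    def test_sign_follows_pi_minus_theta(self, rng):
        for _ in range(20):
            S = int(rng.integers(1, 50))
            pi_sum = float(rng.uniform(0, 20))
            d = ps.window_tajimas_d(pi_sum, S, 20)
            expected_sign = np.sign(pi_sum - ps.window_theta_w(S, 20))
            assert np.sign(d) == expected_sign or d == 0

    def test_undefined_without_snps(self):
        assert np.isnan(ps.window_tajimas_d(0.0, 0, 20))


class TestBruteForceOracle:
    """Direct summation reproduces every windowed operation to 1e-12."""

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_weighted_ops_match_direct_sums(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 21))
        c, sigma = 90_000, 30_000
        pos = r.integers(c - 3 * sigma, c + 3 * sigma + 1, size=n)
        fst = r.uniform(0, 1, size=n)
        dxy = r.uniform(0, 0.8, size=n)
        w = [math.exp(-((p - c) ** 2) / (2 * sigma**2)) for p in pos]
        fst_direct = sum(wi * fi for wi, fi in zip(w, fst)) / sum(w)
        W = sum(
            math.exp(-(k**2) / (2 * sigma**2)) for k in range(-3 * sigma, 3 * sigma + 1)
        )
        dxy_direct = sum(wi * di for wi, di in zip(w, dxy)) / W
        assert ps.weighted_window_fst(fst, pos, c, sigma) == pytest.approx(
            fst_direct, abs=1e-12
        )
        assert ps.weighted_window_dxy(dxy, pos, c, sigma) == pytest.approx(
            dxy_direct, abs=1e-12
        )
        C = 20
        j = r.integers(0, C + 1, size=n)
        pi_direct = sum(2 * jj * (C - jj) / (C * (C - 1)) for jj in j) / 180_000
        assert ps.window_pi(j, C, 180_000) == pytest.approx(pi_direct, abs=1e-12)

    def test_weighted_average_bounded_by_inputs(self, rng):
        pos = rng.integers(0, 180_001, size=30)
        fst = rng.uniform(0, 1, size=30)
        val = ps.weighted_window_fst(fst, pos, 90_000, 30_000)
        assert fst.min() - 1e-12 <= val <= fst.max() + 1e-12


class TestScanWindows:
    def test_rows_match_directly_computed_windows(self):
        lg_lengths = {"LG01": 200_000}
        per_snp = pd.DataFrame(
            {
                "lg": "LG01",
                "pos": [50_000, 90_000, 150_000],
                "fst": [0.1, 0.2, np.nan],
                "dxy": [0.3, 0.5, 0.2],
                "p_X": [0.4, 0.5, 0.45],
            }
        )
        w = ps.scan_windows(per_snp, lg_lengths, superpool_ploidies={"X": 40})
        assert w["center"].tolist() == [90_000, 110_000]
        first = w.iloc[0]
        assert first["n_snps"] == 2
        assert first["weighted_fst"] == pytest.approx(
            ps.weighted_window_fst([0.1, 0.2], [50_000, 90_000], 90_000, 30_000)
        )
        assert first["weighted_dxy"] == pytest.approx(
            ps.weighted_window_dxy([0.3, 0.5, 0.2], per_snp["pos"], 90_000, 30_000)
        )
        j = np.rint(per_snp["p_X"].to_numpy() * 40)
        assert first["pi_X"] == pytest.approx(ps.window_pi(j, 40, 180_000))
        assert first["tajd_X"] == pytest.approx(
            ps.window_tajimas_d(ps.window_pi_sum(j, 40), 2, 40)
        )

    def test_empty_window_reported_with_zero_snps(self):
        per_snp = pd.DataFrame(
            {"lg": ["LG01"], "pos": [1_000_000], "fst": [0.1], "dxy": [0.1]}
        )
        w = ps.scan_windows(per_snp, {"LG01": 1_200_000, "LG02": 180_000})
        lg2 = w[w["lg"] == "LG02"]
        assert len(lg2) == 1
        assert lg2.iloc[0]["n_snps"] == 0
        assert np.isnan(lg2.iloc[0]["weighted_fst"])

    def test_null_window_mean_matches_per_snp_mean(self, null_dataset, null_config):
        """On uniform-divergence data the window field is centered on the
        per-SNP mean F_ST (kernel smoothing is unbiased)."""
        from conftest import run_scan

        matrix, _ = null_dataset
        _, per_snp, windows = run_scan(matrix, null_config.lg_lengths)
        snp_mean = per_snp["fst"].dropna().mean()
        win_mean = windows["weighted_fst"].dropna().mean()
        assert win_mean == pytest.approx(snp_mean, abs=3 * per_snp["fst"].dropna().std() / 30)
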