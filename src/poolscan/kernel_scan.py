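"""Gaussian kernel-smoothed sliding-window scan (KSMWA) with pooled diversity.

Windows of full span 6σ (±3σ around each center, 180 kb at the defaults
σ = 30 kb) slide along each linkage group by a fixed step (20 kb), so
consecutive windows overlap heavily and the window series is a smoothed field.
Within a window the contribution of the SNP at position p is weighted by
exp(−(p−c)²/2σ²); the kernel is truncated at ±3σ, the only span consistent
with a 180 kb window at σ = 30 kb.

Per window the scan reports:

* weighted F_ST — kernel-weighted mean over SNPs with defined per-SNP F_ST
  (variable sites only; a window with no such SNPs gets NaN and S_n = 0);
* weighted d_XY — kernel-weighted SNP sum divided by the kernel mass W summed
  over *every* integer bp of the span, making it a per-bp quantity
  (monomorphic sites contribute zero, so only SNPs enter the numerator);
* π per superpool — Σ 2j(C−j)/(C(C−1)) over sites, divided by the window
  length n in bp (j = reference-allele count at the superpool ploidy C; the
  term is symmetric in j so the reference/derived labelling is immaterial);
* Watterson's θ_W per superpool — S_n / Σ 1/i, summing by default to C−1
  (standard Watterson); the printed-formula variant summing to C is available
  via ``theta_sum_upper="C"``;
* Tajima's D per superpool — (π_sum − θ_W)/√var with the Tajima (1989)
  constants at sample size C, where π_sum is the per-window π total (not
  divided by n) so that π and θ_W are on the same per-window scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .pool_io import ContractError


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window geometry: step and kernel width in bp."""

    step: int = 20_000
    sigma: int = 30_000

    @property
    def half_span(self) -> int:
        return 3 * self.sigma

    @property
    def span(self) -> int:
        return 2 * self.half_span

    def kernel_mass_per_bp(self) -> float:
        """W: kernel weight summed over every integer bp offset in [−3σ, 3σ]."""
        return _kernel_mass(self.sigma)


@lru_cache(maxsize=8)
def _kernel_mass(sigma: int) -> float:
    offsets = np.arange(-3 * sigma, 3 * sigma + 1, dtype=float)
    return float(np.exp(-(offsets**2) / (2.0 * float(sigma) ** 2)).sum())


def make_windows(lg_lengths: dict[str, int], scheme: WindowScheme) -> dict[str, np.ndarray]:
    """Window centers per linkage group.

    Centers start at half_span and advance by step while the full window still
    fits (center + half_span ≤ length); windows never span linkage groups.  A
    linkage group shorter than one window yields an empty center array.
    """
    out = {}
    for lg, length in lg_lengths.items():
        if length <= 0:
            raise ContractError(f"non-positive length for linkage group {lg}")
        hs = scheme.half_span
        out[lg] = (
            np.arange(hs, length - hs + 1, scheme.step, dtype=np.int64)
            if length >= 2 * hs
            else np.empty(0, dtype=np.int64)
        )
    return out


def kernel_weight(p, c, sigma):
    """Gaussian kernel exp(−(p−c)²/2σ²), defined as 0 beyond ±3σ."""
    p = np.asarray(p, dtype=float)
    d = p - float(c)
    w = np.where(np.abs(d) <= 3.0 * sigma, np.exp(-(d**2) / (2.0 * float(sigma) ** 2)), 0.0)
    return float(w) if w.ndim == 0 else w


def weighted_window_fst(per_snp_fst, positions, c, sigma) -> float:
    """Kernel-weighted mean F_ST over SNPs with a defined per-SNP value.

    Returns NaN when no SNP in the span has a defined F_ST.
    """
    fst = np.asarray(per_snp_fst, dtype=float)
    w = kernel_weight(positions, c, sigma)
    ok = (w > 0) & ~np.isnan(fst)
    if not np.any(ok):
        return np.nan
    return float(np.sum(w[ok] * fst[ok]) / np.sum(w[ok]))


def weighted_window_dxy(per_snp_dxy, positions, c, sigma) -> float:
    """Per-bp kernel-weighted d_XY: SNP-weighted sum over the full kernel mass W.

    Monomorphic sites contribute 0, so they appear only through W.
    """
    vals = np.asarray(per_snp_dxy, dtype=float)
    w = kernel_weight(positions, c, sigma)
    ok = (w > 0) & ~np.isnan(vals)
    num = float(np.sum(w[ok] * vals[ok])) if np.any(ok) else 0.0
    return num / _kernel_mass(int(sigma))


def window_pi(j_counts, superpool_ploidy: int, window_len: int) -> float:
    """Nucleotide diversity per bp: Σ 2j(C−j)/(C(C−1)) over sites, / n."""
    return window_pi_sum(j_counts, superpool_ploidy) / float(window_len)


def window_pi_sum(j_counts, superpool_ploidy: int) -> float:
    """Per-window π total (not divided by window length)."""
    C = superpool_ploidy
    if C < 2:
        raise ContractError("superpool ploidy must be >= 2")
    j = np.asarray(j_counts, dtype=float)
    if np.any((j < 0) | (j > C)):
        raise ContractError("allele counts outside [0, C]")
    return float(np.sum(2.0 * j * (C - j)) / (C * (C - 1.0)))


def harmonic_number(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def window_theta_w(s_n: int, superpool_ploidy: int, theta_sum_upper: str = "C-1") -> float:
    """Watterson's θ_W = S_n / a1 with a1 = Σ 1/i up to C−1 (or C)."""
    C = superpool_ploidy
    if C < 2:
        raise ContractError("superpool ploidy must be >= 2")
    if s_n < 0:
        raise ContractError("negative number of segregating sites")
    upper = C - 1 if theta_sum_upper == "C-1" else C
    return s_n / harmonic_number(upper)


@lru_cache(maxsize=64)
def tajima_constants(C: int) -> dict[str, float]:
    """Tajima (1989) variance constants for sample size C."""
    a1 = harmonic_number(C - 1)
    a2 = float(np.sum(1.0 / np.arange(1, C) ** 2))
    b1 = (C + 1.0) / (3.0 * (C - 1.0))
    b2 = 2.0 * (C**2 + C + 3.0) / (9.0 * C * (C - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (C + 2.0) / (a1 * C) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def window_tajimas_d(pi_sum: float, s_n: int, superpool_ploidy: int) -> float:
    """Tajima's D = (π_sum − θ_W)/√(e1·S + e2·S(S−1)); NaN when S_n = 0.

    ``pi_sum`` is the per-window π total on the same scale as θ_W.  θ_W here
    always uses the standard Watterson denominator a1 = Σ_{i=1}^{C−1} 1/i,
    which the variance constants assume.
    """
    if s_n == 0:
        return np.nan
    k = tajima_constants(superpool_ploidy)
    theta_w = s_n / k["a1"]
    var = k["e1"] * s_n + k["e2"] * s_n * (s_n - 1.0)
    return float((pi_sum - theta_w) / np.sqrt(var))


# ---------------------------------------------------------------------------
# scan driver
# ---------------------------------------------------------------------------

def scan_windows(
    per_snp: pd.DataFrame,
    lg_lengths: dict[str, int],
    scheme: WindowScheme = WindowScheme(),
    superpool_ploidies: dict[str, int] | None = None,
    theta_sum_upper: str = "C-1",
) -> pd.DataFrame:
    """Run the kernel scan over a per-SNP statistics frame.

    ``per_snp`` needs columns ``lg, pos, fst, dxy`` and, for each superpool
    label in ``superpool_ploidies``, a frequency column ``p_<label>`` used for
    the within-superpool π and Tajima's D.  Returns one row per window with
    columns ``lg, center, span_start, span_end, n_snps, weighted_fst,
    weighted_dxy`` plus ``pi_<label>``, ``theta_w_<label>``, ``tajd_<label>``.
    """
    superpool_ploidies = superpool_ploidies or {}
    centers_by_lg = make_windows(lg_lengths, scheme)
    sigma = scheme.sigma
    hs = scheme.half_span
    rows = []
    for lg, centers in centers_by_lg.items():
        sub = per_snp[per_snp["lg"] == lg]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        fst = sub["fst"].to_numpy(dtype=float)[order]
        dxy_v = sub["dxy"].to_numpy(dtype=float)[order]
        sp_freqs = {
            label: sub[f"p_{label}"].to_numpy(dtype=float)[order]
            for label in superpool_ploidies
        }
        for c in centers:
            lo = np.searchsorted(pos, c - hs, side="left")
            hi = np.searchsorted(pos, c + hs, side="right")
            p_in = pos[lo:hi]
            w = np.exp(-((p_in - float(c)) ** 2) / (2.0 * float(sigma) ** 2))
            f_in = fst[lo:hi]
            ok = ~np.isnan(f_in)
            s_n = int(ok.sum())
            wfst = float(np.sum(w[ok] * f_in[ok]) / np.sum(w[ok])) if s_n else np.nan
            d_in = dxy_v[lo:hi]
            okd = ~np.isnan(d_in)
            wdxy = float(np.sum(w[okd] * d_in[okd])) / _kernel_mass(sigma)
            row = {
                "lg": lg,
                "center": int(c),
                "span_start": int(c - hs),
                "span_end": int(c + hs),
                "n_snps": s_n,
                "weighted_fst": wfst,
                "weighted_dxy": wdxy,
            }
            for label, C in superpool_ploidies.items():
                freqs_in = sp_freqs[label][lo:hi]
                okf = ~np.isnan(freqs_in)
                j = np.rint(freqs_in[okf] * C)
                pi_total = window_pi_sum(j, C)
                row[f"pi_{label}"] = pi_total / float(scheme.span)
                row[f"theta_w_{label}"] = window_theta_w(s_n, C, theta_sum_upper)
                row[f"tajd_{label}"] = window_tajimas_d(pi_total, s_n, C)
            rows.append(row)
    return pd.DataFrame(rows)
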