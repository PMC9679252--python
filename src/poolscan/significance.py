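"""Bootstrap null reference for kernel-weighted F_ST and BH false-discovery rate.

The null model asks: how large a kernel-weighted window average would we see
if per-SNP F_ST values were exchangeable across the genome?  For each window
SNP count n, a bootstrap distribution is built from B replicates; each
replicate draws n per-SNP F_ST values with replacement from the genome-wide
pool, attaches them to n positions drawn uniformly at random in the window
span [c−3σ, c+3σ] (the least-informative way to attach kernel weights to an
unordered draw), and records the kernel-weighted mean.  A window with S_n SNPs
is compared against the distribution for n = min(S_n, n_max); its p-value is
the proportion of replicates greater than or equal to the observed weighted
mean, with resolution floor 1/B.  Benjamini–Hochberg step-up adjustment turns
the window p-values into q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernel_scan import WindowScheme
from .pool_io import ContractError


@dataclass
class NullReference:
    """Sorted bootstrap distributions of kernel-weighted F_ST, keyed by n."""

    label: str
    sigma: int
    n_max: int
    B: int
    seed: int
    distributions: dict[int, np.ndarray] = field(default_factory=dict)

    def distribution_for(self, s_n: int) -> np.ndarray:
        if s_n < 1:
            raise ContractError("no null distribution for windows without SNPs")
        n = min(s_n, self.n_max)
        try:
            return self.distributions[n]
        except KeyError:
            raise KeyError(f"null reference has no distribution for n={n}") from None

    # -- binary-free persistence -------------------------------------------

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# null-reference label={self.label} seed={self.seed} "
                f"B={self.B} sigma={self.sigma} n_max={self.n_max}\n"
            )
            for n in sorted(self.distributions):
                vals = " ".join(f"{v:.8g}" for v in self.distributions[n])
                fh.write(f"{n}\t{vals}\n")

    @classmethod
    def read(cls, path) -> "NullReference":
        with open(path) as fh:
            header = fh.readline().strip()
            meta = dict(
                kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv
            )
            ref = cls(
                label=meta.get("label", "null-reference"),
                sigma=int(meta["sigma"]),
                n_max=int(meta["n_max"]),
                B=int(meta["B"]),
                seed=int(meta["seed"]),
            )
            for line in fh:
                n_str, vals = line.split("\t", 1)
                ref.distributions[int(n_str)] = np.fromstring(vals, sep=" ")
        return ref


def build_null_reference(
    per_snp_fst,
    scheme: WindowScheme = WindowScheme(),
    n_max: int = 2000,
    B: int = 10_000,
    seed: int = 0,
    n_values=None,
    label: str = "comparison",
) -> NullReference:
    """Bootstrap distributions of kernel-weighted F_ST for each window size n.

    ``n_values`` restricts the build to the window SNP counts actually needed
    (capped at ``n_max``); by default every n in 1..n_max is built, which at
    the study-scale defaults (n_max 2000, B 10^6) is a large computation.
    """
    fst = np.asarray(per_snp_fst, dtype=float)
    fst = fst[~np.isnan(fst)]
    if fst.size == 0:
        raise ContractError("empty per-SNP F_ST pool")
    if n_max < 1:
        raise ContractError("n_max must be >= 1")
    if B < 1:
        raise ContractError("B must be >= 1")
    if n_values is None:
        needed = range(1, n_max + 1)
    else:
        needed = sorted({min(int(n), n_max) for n in n_values if n >= 1})
    rng = np.random.default_rng(seed)
    hs = float(scheme.half_span)
    two_sig2 = 2.0 * float(scheme.sigma) ** 2
    ref = NullReference(label, scheme.sigma, n_max, B, seed)
    for n in needed:
        draws = fst[rng.integers(0, fst.size, size=(B, n))]
        offsets = rng.uniform(-hs, hs, size=(B, n))
        w = np.exp(-(offsets**2) / two_sig2)
        reps = np.sum(w * draws, axis=1) / np.sum(w, axis=1)
        reps.sort()
        ref.distributions[n] = reps
    return ref


def window_pvalue(weighted_fst: float, s_n: int, null: NullReference) -> float:
    """p = (# bootstrap replicates ≥ observed)/B; NaN sentinel when S_n = 0."""
    if s_n == 0 or np.isnan(weighted_fst):
        return np.nan
    dist = null.distribution_for(s_n)
    idx = np.searchsorted(dist, weighted_fst, side="left")
    return float((dist.size - idx) / dist.size)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, original order restored.

    q_(i) = min_{k≥i} p_(k)·m/k over the ascending order statistics; NaN
    entries (undefined windows) are passed through and excluded from m.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ContractError("p-values outside [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


def attach_significance(
    windows: pd.DataFrame, null: NullReference
) -> pd.DataFrame:
    """Add ``pvalue`` and ``qvalue`` columns to a window scan frame.

    Windows with S_n = 0 receive NaN for both and are excluded from the FDR
    adjustment.
    """
    out = windows.copy()
    out["pvalue"] = [
        window_pvalue(f, n, null)
        for f, n in zip(out["weighted_fst"], out["n_snps"])
    ]
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out
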