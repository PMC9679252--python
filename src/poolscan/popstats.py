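"""Per-SNP and per-pool population statistics for pooled allele frequencies.

Implements the estimators the divergence scan is built on:

* Nei F_ST from expected heterozygosities, F_ST = (H_T − H_S) / H_T with
  H_T = 2 p̄ (1 − p̄) over the unweighted group-mean frequency and H_S the mean
  expected heterozygosity within groups.  This plain estimator is upwardly
  biased for pooled data; the bias is consistent across pools of similar depth
  and sample size, which is why relative comparisons remain meaningful (a
  bias-corrected estimator is deliberately out of scope).
* d_XY for unphased data, d_XY = p_X q_Y + q_X p_Y.
* Lin's concordance correlation coefficient between replicate pools.
* A global pairwise F_ST matrix (single genome-wide window over all SNPs).
* A folded minor-allele-spectrum QC that flags pools with an excess of
  low-frequency variants (the symptom that led to excluding one pool from
  environmental-association runs in the motivating study design).

Superpool frequencies are unweighted arithmetic means of member pool
frequencies; group weighting in F_ST is equal by default with an optional
ploidy weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pool_io import ContractError, PoolAlleleMatrix

#: sentinel for statistics undefined at a site (e.g. H_T = 0)
UNDEFINED = np.nan


@dataclass(frozen=True)
class SuperpoolSpec:
    """A group of pools treated as one population."""

    label: str
    members: tuple[str, ...]

    def effective_ploidy(self, pool_ploidy: int = 20) -> int:
        return pool_ploidy * len(self.members)


@dataclass
class ConcordanceResult:
    """Lin's concordance between two frequency vectors (n-denominator moments)."""

    pool_a: str
    pool_b: str
    rho_c: float
    pearson: float
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    n_snps: int


def superpool_frequency(pool_freqs) -> float | np.ndarray:
    """Unweighted arithmetic mean of member pool frequencies.

    Accepts a 1-D sequence (one SNP) or a 2-D array (snps x pools, averaged
    over the pool axis).
    """
    arr = np.asarray(pool_freqs, dtype=float)
    if arr.size == 0:
        raise ContractError("superpool_frequency of empty pool list")
    if arr.ndim == 1:
        return float(arr.mean())
    return arr.mean(axis=1)


def fst_nei(p_groups, weights=None):
    """Nei F_ST = (H_T − H_S)/H_T from per-group frequencies.

    ``p_groups`` is a sequence of ≥2 frequencies (one SNP) or a 2-D array of
    shape (snps, groups).  Sites with H_T = 0 return NaN.  ``weights`` gives
    optional per-group weights (e.g. superpool ploidies); default equal.
    """
    arr = np.atleast_2d(np.asarray(p_groups, dtype=float))
    if arr.shape[1] < 2:
        raise ContractError("fst_nei requires at least two groups")
    if weights is None:
        w = np.full(arr.shape[1], 1.0 / arr.shape[1])
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    pbar = arr @ w
    h_t = 2.0 * pbar * (1.0 - pbar)
    h_s = (2.0 * arr * (1.0 - arr)) @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), UNDEFINED)
    return float(fst[0]) if np.asarray(p_groups).ndim == 1 else fst


def dxy(p_x, p_y):
    """Absolute divergence for unphased data: p_X q_Y + q_X p_Y (symmetric)."""
    p_x = np.asarray(p_x, dtype=float)
    p_y = np.asarray(p_y, dtype=float)
    out = p_x * (1.0 - p_y) + (1.0 - p_x) * p_y
    return float(out) if out.ndim == 0 else out


def lin_ccc(x, y, pool_a: str = "x", pool_b: str = "y") -> ConcordanceResult:
    """Lin's concordance correlation ρ_c = 2ρσ_Xσ_Y / (σ²_X + σ²_Y + (μ_X−μ_Y)²).

    Moments use the population (n-denominator) convention, under which
    ρ_c = 1 exactly iff x = y elementwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ContractError("lin_ccc requires two equal-length vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # ddof=0
    if vx == 0 and vy == 0:
        raise ContractError("lin_ccc undefined: both vectors constant")
    cov = ((x - mx) * (y - my)).mean()
    denom_r = np.sqrt(vx * vy)
    pearson = cov / denom_r if denom_r > 0 else np.nan
    rho_c = 2.0 * cov / (vx + vy + (mx - my) ** 2)
    return ConcordanceResult(
        pool_a, pool_b, float(rho_c), float(pearson), float(mx), float(my),
        float(vx), float(vy), len(x),
    )


def concordance_table(m: PoolAlleleMatrix) -> pd.DataFrame:
    """Lin's ρ_c and Pearson ρ for every pool pair of a matrix."""
    freqs = m.frequencies()
    rows = []
    for i in range(m.n_pools):
        for j in range(i + 1, m.n_pools):
            ok = ~np.isnan(freqs[:, i]) & ~np.isnan(freqs[:, j])
            res = lin_ccc(
                freqs[ok, i], freqs[ok, j], m.pools[i].pool_id, m.pools[j].pool_id
            )
            rows.append(
                {
                    "pool_a": res.pool_a,
                    "pool_b": res.pool_b,
                    "rho_c": res.rho_c,
                    "pearson": res.pearson,
                    "n_snps": res.n_snps,
                }
            )
    return pd.DataFrame(rows)


def per_snp_stats(
    m: PoolAlleleMatrix,
    superpool_x: SuperpoolSpec,
    superpool_y: SuperpoolSpec,
    weights: str = "equal",
) -> pd.DataFrame:
    """Superpool frequencies, per-SNP Nei F_ST and d_XY for one comparison.

    Returns a frame with columns ``lg, pos, p_x, p_y, fst, dxy``; F_ST is NaN
    at sites monomorphic across both superpools.  ``weights='ploidy'`` weights
    the two groups by superpool ploidy instead of equally.
    """
    freqs = m.frequencies()
    ix = [m.pool_index(p) for p in superpool_x.members]
    iy = [m.pool_index(p) for p in superpool_y.members]
    p_x = superpool_frequency(freqs[:, ix])
    p_y = superpool_frequency(freqs[:, iy])
    if weights == "ploidy":
        w = [superpool_x.effective_ploidy(), superpool_y.effective_ploidy()]
    elif weights == "equal":
        w = None
    else:
        raise ContractError(f"unknown weighting {weights!r}")
    fst = fst_nei(np.column_stack([p_x, p_y]), weights=w)
    return pd.DataFrame(
        {
            "lg": m.snps["lg"].to_numpy(),
            "pos": m.snps["pos"].to_numpy(),
            "p_x": p_x,
            "p_y": p_y,
            "fst": fst,
            "dxy": dxy(p_x, p_y),
        }
    )


def pairwise_global_fst(m: PoolAlleleMatrix) -> pd.DataFrame:
    """Genome-wide pairwise F_ST between all pools (one whole-genome window).

    For each pool pair, the unweighted mean of per-SNP Nei F_ST over SNPs with
    H_T > 0 for that pair; symmetric with a zero diagonal.
    """
    if m.n_pools < 2:
        raise ContractError("pairwise_global_fst requires at least two pools")
    freqs = m.frequencies()
    n = m.n_pools
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(freqs[:, i]) & ~np.isnan(freqs[:, j])
            fst = fst_nei(np.column_stack([freqs[ok, i], freqs[ok, j]]))
            val = np.nanmean(fst) if np.any(~np.isnan(fst)) else np.nan
            out[i, j] = out[j, i] = val
    ids = m.pool_ids
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# allele-spectrum QC
# ---------------------------------------------------------------------------

def minor_allele_spectrum(pool_freqs, ploidy: int = 20) -> pd.Series:
    """Histogram of folded minor-allele frequencies on the grid {0, 1/C, ..., 0.5}.

    Input frequencies must lie on the 1/C grid (the Pool-Seq quantization).
    """
    p = np.asarray(pool_freqs, dtype=float)
    p = p[~np.isnan(p)]
    grid = np.rint(p * ploidy)
    if not np.allclose(grid / ploidy, p, atol=1e-9):
        raise ContractError("frequencies not on the 1/C ploidy grid")
    maf = np.minimum(grid, ploidy - grid).astype(int)
    bins = np.arange(ploidy // 2 + 1)
    counts = np.bincount(maf, minlength=len(bins))[: len(bins)]
    return pd.Series(counts, index=bins / ploidy, name="n_snps")


def flag_skewed_pools(
    m: PoolAlleleMatrix, max_maf_bins: int = 2, z_threshold: float = 3.0
) -> pd.DataFrame:
    """Flag pools whose share of SNPs at MAF ≤ max_maf_bins/C is an outlier.

    A pool is flagged when its low-MAF share exceeds the across-pool mean by
    more than ``z_threshold`` standard deviations (computed leaving the pool
    out).  Mirrors the replicate-QC step that catches a skewed allele-frequency
    distribution in a single pool.
    """
    freqs = m.frequencies()
    shares = []
    for j, pool in enumerate(m.pools):
        spec = minor_allele_spectrum(freqs[:, j], pool.ploidy)
        low = spec.iloc[1 : max_maf_bins + 1].sum()  # exclude monomorphic bin 0
        total = spec.iloc[1:].sum()
        shares.append(low / total if total else np.nan)
    shares = np.asarray(shares)
    rows = []
    for j, pool in enumerate(m.pools):
        others = np.delete(shares, j)
        mu, sd = np.nanmean(others), np.nanstd(others, ddof=1)
        z = (shares[j] - mu) / sd if sd > 0 else 0.0
        rows.append(
            {
                "pool_id": pool.pool_id,
                "low_maf_share": shares[j],
                "zscore": z,
                "flagged": bool(z > z_threshold),
            }
        )
    return pd.DataFrame(rows)
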