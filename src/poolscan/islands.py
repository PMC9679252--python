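"""Calling and summarizing islands of differentiation from window series.

An island is a maximal run of at least ``min_run`` consecutive windows (center
spacing exactly one step; a gap at a short linkage-group end breaks a run)
whose kernel-weighted F_ST exceeds a threshold (default 0.03, chosen in the
motivating design as the level containing the upper 10% of window values; a
quantile-based alternative is provided).  The island interval is
[first_center − step/2, last_center + step/2], so its length is exactly
n_windows × step and can be smaller than one full window span.

Island summaries mirror the genome-scan reporting conventions: mean weighted
F_ST and d_XY over member windows, counts of windows with d_XY above the
genome-wide upper 5% quantile and above the genome-wide mean, and per-
superpool mean Tajima's D and π with counts of windows below the genome-wide
lower 5% quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pool_io import ContractError


@dataclass
class Island:
    """A maximal qualifying run of windows with its genomic extent."""

    id: str
    lg: str
    first_center: int
    last_center: int
    n_windows: int
    start: int  # first_center - step/2
    end: int    # last_center + step/2
    mean_weighted_fst: float = np.nan
    mean_weighted_dxy: float = np.nan
    n_dxy_above_q95: int = 0
    n_dxy_above_mean: int = 0
    superpool_stats: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


def find_outlier_windows(qvalues, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of windows with q < alpha (NaN q never qualifies)."""
    q = np.asarray(qvalues, dtype=float)
    with np.errstate(invalid="ignore"):
        return (q < alpha) & ~np.isnan(q)


def fst_threshold_from_quantile(window_fst, q: float = 0.90) -> float:
    """Linear-interpolation quantile of window weighted F_ST values."""
    vals = np.asarray(window_fst, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ContractError("no defined window F_ST values")
    return float(np.quantile(vals, q))


def find_islands(
    windows: pd.DataFrame,
    threshold: float = 0.03,
    min_run: int = 4,
    step: int = 20_000,
) -> list[Island]:
    """Maximal runs of ≥ min_run consecutive windows with weighted F_ST > threshold.

    ``windows`` needs columns ``lg, center, weighted_fst`` ordered by center
    within each linkage group.  Runs require exact ``step`` spacing between
    consecutive centers and never cross linkage groups; islands are numbered
    left to right within each linkage group (``<lg>_1``, ``<lg>_2``, ...).
    """
    islands: list[Island] = []
    for lg, grp in windows.groupby("lg", sort=False):
        grp = grp.sort_values("center")
        centers = grp["center"].to_numpy(dtype=np.int64)
        fst = grp["weighted_fst"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            above = (fst > threshold) & ~np.isnan(fst)
        k = 0
        i = 0
        n = len(centers)
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < n
                and above[j + 1]
                and centers[j + 1] - centers[j] == step
            ):
                j += 1
            run_len = j - i + 1
            if run_len >= min_run:
                k += 1
                islands.append(
                    Island(
                        id=f"{lg}_{k}",
                        lg=str(lg),
                        first_center=int(centers[i]),
                        last_center=int(centers[j]),
                        n_windows=run_len,
                        start=int(centers[i] - step // 2),
                        end=int(centers[j] + step // 2),
                    )
                )
            i = j + 1
    return islands


def genome_quantiles(
    windows: pd.DataFrame, superpools: list[str] | None = None
) -> dict:
    """Genome-wide reference quantiles used by island summaries."""
    dxy = windows["weighted_dxy"].to_numpy(dtype=float)
    dxy = dxy[~np.isnan(dxy)]
    out = {
        "dxy_q95": float(np.quantile(dxy, 0.95)),
        "dxy_mean": float(np.mean(dxy)),
    }
    for sp in superpools or []:
        for stat in ("tajd", "pi"):
            vals = windows[f"{stat}_{sp}"].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            out[f"{stat}_{sp}_q05"] = float(np.quantile(vals, 0.05))
    return out


def island_summary(
    island: Island,
    windows: pd.DataFrame,
    quantiles: dict,
    superpools: list[str] | None = None,
) -> Island:
    """Populate an island's summary statistics from its member windows."""
    member = windows[
        (windows["lg"] == island.lg)
        & (windows["center"] >= island.first_center)
        & (windows["center"] <= island.last_center)
    ]
    fst = member["weighted_fst"].to_numpy(dtype=float)
    dxy = member["weighted_dxy"].to_numpy(dtype=float)
    island.mean_weighted_fst = float(np.nanmean(fst))
    island.mean_weighted_dxy = float(np.nanmean(dxy))
    island.n_dxy_above_q95 = int(np.sum(dxy > quantiles["dxy_q95"]))
    island.n_dxy_above_mean = int(np.sum(dxy > quantiles["dxy_mean"]))
    for sp in superpools or []:
        tajd = member[f"tajd_{sp}"].to_numpy(dtype=float)
        pi = member[f"pi_{sp}"].to_numpy(dtype=float)
        island.superpool_stats[sp] = {
            "mean_tajd": float(np.nanmean(tajd)),
            "mean_pi": float(np.nanmean(pi)),
            "n_tajd_below_q05": int(np.sum(tajd < quantiles[f"tajd_{sp}_q05"])),
            "n_pi_below_q05": int(np.sum(pi < quantiles[f"pi_{sp}_q05"])),
        }
    return island


def summarize_islands(
    windows: pd.DataFrame,
    islands: list[Island],
    superpools: list[str] | None = None,
) -> pd.DataFrame:
    """Table of populated island summaries (one row per island)."""
    quant = genome_quantiles(windows, superpools)
    rows = []
    for isl in islands:
        island_summary(isl, windows, quant, superpools)
        row = {
            "island_id": isl.id,
            "lg": isl.lg,
            "start": isl.start,
            "end": isl.end,
            "n_windows": isl.n_windows,
            "mean_weighted_fst": isl.mean_weighted_fst,
            "mean_weighted_dxy": isl.mean_weighted_dxy,
            "n_dxy_above_q95": isl.n_dxy_above_q95,
            "n_dxy_above_mean": isl.n_dxy_above_mean,
        }
        for sp, stats in isl.superpool_stats.items():
            for key, val in stats.items():
                row[f"{key}_{sp}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def outlier_cv_per_lg(outlier_mask, lg_labels) -> float:
    """Coefficient of variation of per-linkage-group outlier-window counts.

    Sample standard deviation (ddof=1) divided by the mean count; NaN sentinel
    when the mean is zero.
    """
    mask = np.asarray(outlier_mask, dtype=bool)
    lgs = np.asarray(lg_labels)
    if mask.shape != lgs.shape:
        raise ContractError("mask and linkage-group labels differ in length")
    unique = pd.unique(lgs)
    if len(unique) < 2:
        raise ContractError("outlier_cv_per_lg requires >= 2 linkage groups")
    counts = np.array([int(mask[lgs == lg].sum()) for lg in unique], dtype=float)
    mean = counts.mean()
    if mean == 0:
        return np.nan
    return float(counts.std(ddof=1) / mean)


def islands_to_bed(islands: list[Island]) -> pd.DataFrame:
    """Island intervals as 0-based half-open BED records."""
    return pd.DataFrame(
        [
            {"chrom": isl.lg, "start": isl.start - 1, "end": isl.end, "name": isl.id}
            for isl in islands
        ]
    )
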