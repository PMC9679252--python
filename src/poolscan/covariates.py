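"""Environmental covariates and association-outlier bookkeeping.

The association model itself (a Bayesian covariate model run per pool) is an
external tool; this module consumes its per-SNP log10 Bayes-factor output and
prepares covariate tables for it:

* scalar current velocity from east/north components, w = sqrt(u² + v²);
* z-score scaling of covariates before they go to the association tool;
* convergence checks across replicate association runs (pairwise Pearson
  correlations, with averaging across runs permitted only when all pairs
  exceed a floor);
* counts per island and covariate of SNPs whose run-averaged log10 Bayes
  factor (decibans) exceeds a decisiveness threshold, 30 dB by default;
* the optical-depth → light-transmission conversion: transmission exp(−od),
  so each ln 10 ≈ 2.303 units of optical depth is one decade of light loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pool_io import ContractError

COVARIATE_COLUMNS = ["chlorophyll", "salinity", "temperature", "u", "v"]


@dataclass
class ConvergenceReport:
    covariate: str
    pairwise_pearson: dict[tuple[int, int], float]
    min_correlation: float
    averaging_allowed: bool


def scalar_velocity(u, v):
    """Scalar current velocity w = sqrt(u² + v²) (m/s), rotation-invariant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ContractError("velocity components must be finite")
    w = np.hypot(u, v)
    return float(w) if w.ndim == 0 else w


def read_covariate_table(path) -> pd.DataFrame:
    """Site covariate TSV (site, chlorophyll, salinity, temperature, u, v)
    with scalar velocity appended."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ["site"] + COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ContractError(f"covariate table missing columns {missing}")
    df["velocity"] = scalar_velocity(df["u"].to_numpy(), df["v"].to_numpy())
    return df


def zscore_covariates(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Center and scale covariates to zero mean, unit (ddof=0) variance."""
    columns = columns or [c for c in df.columns if c != "site"]
    out = df.copy()
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        sd = vals.std()
        if sd == 0:
            raise ContractError(f"covariate {col!r} is constant; cannot scale")
        out[col] = (vals - vals.mean()) / sd
    return out


def run_convergence(
    bf_runs, floor: float = 0.9, covariate: str = ""
) -> ConvergenceReport:
    """Pairwise Pearson correlations among replicate association runs.

    ``bf_runs`` is a sequence of ≥2 equal-length statistic vectors (one per
    run).  Averaging across runs is only sanctioned when every pairwise
    correlation exceeds ``floor``.
    """
    runs = [np.asarray(r, dtype=float) for r in bf_runs]
    if len(runs) < 2:
        raise ContractError("need at least two replicate runs")
    length = len(runs[0])
    if length < 3 or any(len(r) != length for r in runs):
        raise ContractError("runs must share a common length >= 3")
    if any(np.std(r) == 0 for r in runs):
        raise ContractError("constant run vector; correlation undefined")
    pairwise = {}
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            pairwise[(i, j)] = float(np.corrcoef(runs[i], runs[j])[0, 1])
    min_corr = min(pairwise.values())
    return ConvergenceReport(covariate, pairwise, min_corr, min_corr > floor)


def average_bf_runs(bf: pd.DataFrame) -> pd.DataFrame:
    """Average log10 Bayes factors over replicate runs.

    Input columns: ``lg, pos, covariate, run, log10_bf``; output one row per
    (lg, pos, covariate) with the run mean, which necessarily lies between the
    replicate extremes.
    """
    required = {"lg", "pos", "covariate", "run", "log10_bf"}
    missing = required - set(bf.columns)
    if missing:
        raise ContractError(f"Bayes-factor table missing columns {sorted(missing)}")
    return (
        bf.groupby(["lg", "pos", "covariate"], as_index=False)["log10_bf"]
        .mean()
        .rename(columns={"log10_bf": "mean_log10_bf"})
    )


def tabulate_bf_outliers(
    bf_mean: pd.DataFrame, islands, threshold_db: float = 30.0
) -> pd.DataFrame:
    """Per-island, per-covariate counts of SNPs with averaged BF > threshold.

    ``bf_mean`` is the output of :func:`average_bf_runs`; ``islands`` is a
    list of :class:`poolscan.islands.Island` or a frame with ``island_id, lg,
    start, end`` (1-based inclusive).  Counts are monotone non-increasing in
    the threshold.
    """
    if isinstance(islands, pd.DataFrame):
        rows = [
            (str(r["island_id"]), str(r["lg"]), int(r["start"]), int(r["end"]))
            for _, r in islands.iterrows()
        ]
    else:
        rows = [(i.id, i.lg, i.start, i.end) for i in islands]
    covs = sorted(bf_mean["covariate"].unique())
    out = []
    for isl_id, lg, start, end in rows:
        sub = bf_mean[
            (bf_mean["lg"] == lg) & (bf_mean["pos"] >= start) & (bf_mean["pos"] <= end)
        ]
        row = {"island_id": isl_id}
        for cov in covs:
            vals = sub.loc[sub["covariate"] == cov, "mean_log10_bf"]
            row[cov] = int((vals > threshold_db).sum())
        out.append(row)
    return pd.DataFrame(out)


def optical_depth_transmission(od):
    """Fraction of sub-surface downwelling irradiance reaching depth: exp(−od).

    A difference of ln 10 ≈ 2.303 optical-depth units is one order of
    magnitude in light transmission.
    """
    od = np.asarray(od, dtype=float)
    if np.any(od < 0):
        raise ContractError("optical depth must be non-negative")
    t = np.exp(-od)
    return float(t) if t.ndim == 0 else t
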