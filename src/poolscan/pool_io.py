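"""Pooled allele-count data: container, native TSV and sync I/O, SNP filters.

Pool-Seq genotyping reports, for every SNP, a reference-allele count per pool
on a fixed ploidy grid (C allele copies per pool per locus, so frequencies are
multiples of 1/C).  :class:`PoolAlleleMatrix` is the in-memory form consumed by
every downstream module.

Two input dialects are supported:

* native TSV — columns ``lg  pos  ref  alt  <pool_1> ... <pool_k>`` holding
  integer reference-allele counts in ``0..C`` with ``.`` for missing.  This is
  the round-trippable format because it preserves the ploidy quantization.
* PoPoolation2 ``sync`` — ``lg  pos  ref  A:T:C:G:N:del`` per pool.  Read-only;
  read counts are collapsed to the two most frequent alleles overall and
  converted to the ploidy grid by rounding the depth-based frequency to the
  nearest 1/C.

Read depths, needed by :func:`filter_depth`, travel in an optional sidecar TSV
of identical shape (the native dialect itself has no depth columns).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: sentinel for a missing per-pool count
MISSING = -1

SNP_COLUMNS = ["lg", "pos", "ref", "alt"]

_SYNC_BASES = ("A", "T", "C", "G")


class PoolDataError(ValueError):
    """Malformed pooled input; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ContractError(ValueError):
    """A precondition of an operation was violated by the caller."""


@dataclass(frozen=True)
class PoolInfo:
    """Per-pool metadata: identifier, ploidy C and superpool label."""

    pool_id: str
    ploidy: int = 20
    superpool: str = ""


@dataclass
class PoolAlleleMatrix:
    """Per-SNP × per-pool reference-allele counts at fixed ploidy.

    Attributes
    ----------
    snps : DataFrame with columns ``lg, pos, ref, alt`` (pos is 1-based);
        positions strictly increasing within each linkage group.  An optional
        boolean ``multiallelic`` column flags collapsed >2-allele sites.
    counts : int array (n_snps, n_pools); reference-allele counts in
        ``[0, ploidy]`` with :data:`MISSING` for absent calls.
    pools : ordered pool metadata.
    depths : optional int array (n_snps, n_pools) of read depths.
    """

    snps: pd.DataFrame
    counts: np.ndarray
    pools: list[PoolInfo]
    depths: np.ndarray | None = None

    def __post_init__(self):
        self.snps = self.snps.reset_index(drop=True)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.snps), len(self.pools)):
            raise PoolDataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.pools)} pools"
            )
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int64)
            if self.depths.shape != self.counts.shape:
                raise PoolDataError("depths shape does not match counts")
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        ploidy = np.array([p.ploidy for p in self.pools])
        present = self.counts != MISSING
        if np.any((self.counts < 0) & present) or np.any(
            present & (self.counts > ploidy[None, :])
        ):
            raise PoolDataError("counts outside [0, ploidy]")
        for lg, grp in self.snps.groupby("lg", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise PoolDataError(
                    f"positions not strictly increasing on linkage group {lg}"
                )

    # -- basic views --------------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def pool_ids(self) -> list[str]:
        return [p.pool_id for p in self.pools]

    def frequencies(self) -> np.ndarray:
        """Reference-allele frequencies counts/C, NaN where missing."""
        ploidy = np.array([p.ploidy for p in self.pools], dtype=float)
        freq = self.counts / ploidy[None, :]
        return np.where(self.counts == MISSING, np.nan, freq)

    def subset(self, mask: np.ndarray) -> "PoolAlleleMatrix":
        mask = np.asarray(mask, dtype=bool)
        return PoolAlleleMatrix(
            snps=self.snps.loc[mask].reset_index(drop=True),
            counts=self.counts[mask],
            pools=list(self.pools),
            depths=None if self.depths is None else self.depths[mask],
        )

    def pool_index(self, pool_id: str) -> int:
        try:
            return self.pool_ids.index(pool_id)
        except ValueError:
            raise KeyError(f"unknown pool {pool_id!r}") from None

    def superpool_members(self) -> dict[str, list[int]]:
        """Column indices per superpool label, in pool order."""
        out: dict[str, list[int]] = {}
        for j, p in enumerate(self.pools):
            out.setdefault(p.superpool, []).append(j)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, PoolAlleleMatrix):
            return NotImplemented
        same_depths = (
            (self.depths is None) == (other.depths is None)
            and (self.depths is None or np.array_equal(self.depths, other.depths))
        )
        return (
            self.snps[SNP_COLUMNS].equals(other.snps[SNP_COLUMNS])
            and np.array_equal(self.counts, other.counts)
            and self.pools == other.pools
            and same_depths
        )


# ---------------------------------------------------------------------------
# native TSV
# ---------------------------------------------------------------------------

def write_pool_table(
    m: PoolAlleleMatrix, path, provenance: list[str] | None = None
) -> None:
    """Write the native TSV dialect; ``provenance`` lines become ``#`` comments."""
    df = m.snps[SNP_COLUMNS].copy()
    for j, p in enumerate(m.pools):
        col = m.counts[:, j].astype(object)
        col[m.counts[:, j] == MISSING] = "."
        df[p.pool_id] = col
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_depth_table(m: PoolAlleleMatrix, path) -> None:
    if m.depths is None:
        raise ContractError("matrix carries no depths")
    df = m.snps[["lg", "pos"]].copy()
    for j, p in enumerate(m.pools):
        df[p.pool_id] = m.depths[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_pool_table(
    path,
    format: str = "tsv",
    ploidy: int = 20,
    superpools: dict[str, str] | None = None,
    depths_path=None,
) -> PoolAlleleMatrix:
    """Read pooled allele counts from ``tsv`` (native) or ``sync`` input.

    ``superpools`` maps pool_id -> superpool label for the pool metadata;
    unlisted pools get an empty label.
    """
    if format == "tsv":
        m = _read_native_tsv(path, ploidy, superpools)
    elif format == "sync":
        m = _read_sync(path, ploidy, superpools)
    else:
        raise ContractError(f"unknown format {format!r}")
    if depths_path is not None:
        dep = pd.read_csv(depths_path, sep="\t", comment="#")
        depth_cols = [c for c in dep.columns if c not in ("lg", "pos")]
        if depth_cols != m.pool_ids:
            raise PoolDataError("depth table pools do not match count table")
        if len(dep) != m.n_snps:
            raise PoolDataError("depth table rows do not match count table")
        m.depths = dep[depth_cols].to_numpy(dtype=np.int64)
    return m


def _pool_meta(names, ploidy, superpools):
    superpools = superpools or {}
    return [PoolInfo(n, ploidy, superpools.get(n, "")) for n in names]


def _read_native_tsv(path, ploidy, superpools):
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    n_header = 0
    for line in lines:
        if line.startswith("#"):
            n_header += 1
        else:
            break
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    missing_cols = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PoolDataError(f"missing columns {missing_cols}", line=n_header + 1)
    pool_names = [c for c in df.columns if c not in SNP_COLUMNS]
    if not pool_names:
        raise PoolDataError("no pool columns found", line=n_header + 1)

    counts = np.full((len(df), len(pool_names)), MISSING, dtype=np.int64)
    for j, name in enumerate(pool_names):
        col = df[name].astype(str).str.strip()
        is_missing = col == "."
        numeric = pd.to_numeric(col.where(~is_missing), errors="coerce")
        bad = ~is_missing & numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PoolDataError(
                f"non-integer count {col.iloc[row]!r} in pool {name}",
                line=n_header + 2 + row,
            )
        counts[~is_missing.to_numpy(), j] = numeric.dropna().astype(np.int64)

    try:
        pos = pd.to_numeric(df["pos"]).astype(np.int64)
    except (ValueError, TypeError):
        raise PoolDataError("non-integer position", line=n_header + 2) from None
    bad_alt = df["alt"].astype(str).str.contains(",")
    if bad_alt.any():
        row = int(np.flatnonzero(bad_alt.to_numpy())[0])
        raise PoolDataError(
            "more than two alleles in tsv input", line=n_header + 2 + row
        )
    snps = pd.DataFrame(
        {"lg": df["lg"].astype(str), "pos": pos, "ref": df["ref"], "alt": df["alt"]}
    )
    return PoolAlleleMatrix(snps, counts, _pool_meta(pool_names, ploidy, superpools))


def _read_sync(path, ploidy, superpools):
    """PoPoolation2 sync: lg, pos, ref base, then A:T:C:G:N:del per pool."""
    rows = []
    with open(path) as fh:
        raw = [
            (i + 1, line.rstrip("\n"))
            for i, line in enumerate(fh)
            if line.strip() and not line.startswith("#")
        ]
    if not raw:
        raise PoolDataError("empty sync file")
    n_pools = len(raw[0][1].split("\t")) - 3
    if n_pools < 1:
        raise PoolDataError("sync row has no pool columns", line=raw[0][0])
    pool_names = [f"pool{j + 1}" for j in range(n_pools)]

    for lineno, line in raw:
        parts = line.split("\t")
        if len(parts) != 3 + n_pools:
            raise PoolDataError(
                f"expected {3 + n_pools} columns, found {len(parts)}", line=lineno
            )
        lg, pos_s, refchar = parts[:3]
        try:
            pos = int(pos_s)
        except ValueError:
            raise PoolDataError(f"non-integer position {pos_s!r}", line=lineno) from None
        base_counts = np.zeros((n_pools, 4), dtype=np.int64)
        depths = np.zeros(n_pools, dtype=np.int64)
        for j, cell in enumerate(parts[3:]):
            fields = cell.split(":")
            if len(fields) != 6:
                raise PoolDataError(f"malformed sync cell {cell!r}", line=lineno)
            try:
                vals = [int(x) for x in fields]
            except ValueError:
                raise PoolDataError(f"malformed sync cell {cell!r}", line=lineno) from None
            base_counts[j] = vals[:4]
            depths[j] = sum(vals)
        rows.append((lg, pos, refchar.upper(), base_counts, depths))

    snps, counts, depth_rows = [], [], []
    for lg, pos, refchar, base_counts, depths in rows:
        totals = base_counts.sum(axis=0)
        order = np.argsort(-totals, kind="stable")
        top2 = [i for i in order if totals[i] > 0][:2]
        n_alleles = int((totals > 0).sum())
        if not top2:
            top2 = [0, 1]
        if len(top2) == 1:
            top2.append((top2[0] + 1) % 4)
        # keep the sync reference base as the reference allele when it is
        # among the two retained alleles
        ref_idx = _SYNC_BASES.index(refchar) if refchar in _SYNC_BASES else top2[0]
        if ref_idx not in top2:
            ref_idx = top2[0]
        alt_idx = top2[1] if top2[0] == ref_idx else top2[0]
        ref_reads = base_counts[:, ref_idx]
        alt_reads = base_counts[:, alt_idx]
        covered = (ref_reads + alt_reads) > 0
        with np.errstate(invalid="ignore"):
            freq = np.where(covered, ref_reads / np.maximum(ref_reads + alt_reads, 1), 0.0)
        cnt = np.where(covered, np.rint(freq * ploidy).astype(np.int64), MISSING)
        snps.append(
            {
                "lg": lg,
                "pos": pos,
                "ref": _SYNC_BASES[ref_idx],
                "alt": _SYNC_BASES[alt_idx],
                "multiallelic": n_alleles > 2,
            }
        )
        counts.append(cnt)
        depth_rows.append(depths)

    snps_df = pd.DataFrame(snps)
    snps_df["pos"] = snps_df["pos"].astype(np.int64)
    return PoolAlleleMatrix(
        snps_df,
        np.vstack(counts),
        _pool_meta(pool_names, ploidy, superpools),
        depths=np.vstack(depth_rows),
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_depth(
    m: PoolAlleleMatrix, min_depth: int = 20, max_frac: float = 0.02
) -> tuple[PoolAlleleMatrix, pd.DataFrame]:
    """Drop SNPs failing per-pool depth bounds; return (filtered, removal log).

    A SNP is removed when any pool's depth is below ``min_depth`` or above
    ``max_frac`` times that pool's total reads summed over all SNPs of the
    input matrix.
    """
    if m.depths is None:
        raise ContractError("filter_depth requires read depths")
    totals = m.depths.sum(axis=0).astype(float)
    caps = max_frac * totals
    too_low = (m.depths < min_depth).any(axis=1)
    too_high = (m.depths > caps[None, :]).any(axis=1)
    keep = ~(too_low | too_high)
    removed = ~keep
    log = m.snps.loc[removed, ["lg", "pos"]].copy()
    log["reason"] = np.where(too_low[removed], "depth_below_min", "depth_above_cap")
    return m.subset(keep), log.reset_index(drop=True)


def filter_complete_biallelic_variant(m: PoolAlleleMatrix) -> PoolAlleleMatrix:
    """Keep SNPs complete in every pool, biallelic, and variant.

    Removes SNPs with a missing call in any pool, SNPs flagged multi-allelic,
    and SNPs monomorphic across all pools (every pool fixed for the same
    allele: all counts 0, or all counts equal to the pool ploidy).
    """
    ploidy = np.array([p.ploidy for p in m.pools])
    complete = (m.counts != MISSING).all(axis=1)
    all_ref = (m.counts == ploidy[None, :]).all(axis=1)
    all_alt = (m.counts == 0).all(axis=1)
    keep = complete & ~(all_ref | all_alt)
    if "multiallelic" in m.snps.columns:
        keep &= ~m.snps["multiallelic"].to_numpy(dtype=bool)
    return m.subset(keep)
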