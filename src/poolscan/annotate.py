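"""Overlap islands of differentiation with gene annotations.

Gene intervals are read from GFF3 (1-based inclusive) or BED (0-based
half-open) and normalised internally to 0-based half-open coordinates, so a
gene encoded in either format produces the identical interval.  A gene is
reported when its body overlaps an island interval by at least one bp and it
contains at least one SNP; SNP membership is judged against the gene body,
not clipped to the island (the island selects the gene, the gene collects its
SNPs).  Parsing is strict and reports the offending line number, which is why
the two tabular formats are read with pandas plus explicit validation rather
than a database-building annotation library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .pool_io import ContractError, PoolDataError

DEFAULT_FEATURE_TYPES = ("gene", "mRNA")

_NAME_PATTERNS = [re.compile(rf"{key}=([^;]+)") for key in ("Name", "ID", "gene_id")]


@dataclass
class GeneRecord:
    """A gene overlapping an island, with its SNP count and mean F_ST."""

    gene: str
    lg: str
    start: int  # 0-based half-open
    end: int
    n_snps: int
    mean_fst: float
    island_ids: tuple[str, ...]


def _gene_name(attributes: str, fallback: str) -> str:
    for pat in _NAME_PATTERNS:
        m = pat.search(attributes)
        if m:
            return m.group(1)
    return fallback


def read_annotation(
    path, format: str = "gff3", feature_types=DEFAULT_FEATURE_TYPES
) -> pd.DataFrame:
    """Gene intervals as a frame with columns ``gene, lg, start, end, strand``.

    Coordinates are returned 0-based half-open regardless of the input
    convention.  GFF3 rows are filtered to ``feature_types``; BED rows are
    taken as-is.  Malformed rows raise :class:`PoolDataError` with the 1-based
    line number.
    """
    if format == "gff3":
        return _read_gff3(path, feature_types)
    if format == "bed":
        return _read_bed(path)
    raise ContractError(f"unknown annotation format {format!r}")


def _read_gff3(path, feature_types):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise PoolDataError(
                    f"GFF3 row has {len(parts)} columns, expected 9", line=lineno
                )
            seqid, _, ftype, start_s, end_s, _, strand, _, attrs = parts
            if feature_types and ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise PoolDataError(
                    f"non-integer GFF3 coordinates {start_s!r}..{end_s!r}",
                    line=lineno,
                ) from None
            if end < start:
                raise PoolDataError("GFF3 end before start", line=lineno)
            rows.append(
                {
                    "gene": _gene_name(attrs, f"{seqid}:{start}-{end}"),
                    "lg": seqid,
                    "start": start - 1,  # to half-open
                    "end": end,
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "lg", "start", "end", "strand"])


def _read_bed(path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PoolDataError("BED row has fewer than 3 columns", line=lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise PoolDataError("non-integer BED coordinates", line=lineno) from None
            if end <= start:
                raise PoolDataError("empty or inverted BED interval", line=lineno)
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"{parts[0]}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append(
                {"gene": name, "lg": parts[0], "start": start, "end": end, "strand": strand}
            )
    return pd.DataFrame(rows, columns=["gene", "lg", "start", "end", "strand"])


def genes_in_islands(
    islands, genes: pd.DataFrame, snps: pd.DataFrame
) -> list[GeneRecord]:
    """Genes overlapping islands, with per-gene SNP counts and mean F_ST.

    ``islands`` is a list of :class:`poolscan.islands.Island` (1-based
    inclusive intervals) or a frame with ``island_id, lg, start, end``.
    ``snps`` needs ``lg, pos, fst`` (pos 1-based).  Genes containing zero SNPs
    are omitted; output order is by linkage group, gene start, gene name and
    is invariant to input ordering.
    """
    if isinstance(islands, pd.DataFrame):
        island_rows = [
            (str(r["island_id"]), str(r["lg"]), int(r["start"]) - 1, int(r["end"]))
            for _, r in islands.iterrows()
        ]
    else:
        island_rows = [(i.id, i.lg, i.start - 1, i.end) for i in islands]

    island_trees: dict[str, IntervalTree] = {}
    for isl_id, lg, start0, end0 in island_rows:
        island_trees.setdefault(lg, IntervalTree()).addi(start0, end0, isl_id)

    snp_pos: dict[str, np.ndarray] = {}
    snp_fst: dict[str, np.ndarray] = {}
    for lg, grp in snps.groupby("lg", sort=False):
        order = np.argsort(grp["pos"].to_numpy())
        snp_pos[str(lg)] = grp["pos"].to_numpy()[order]
        snp_fst[str(lg)] = grp["fst"].to_numpy(dtype=float)[order]

    records = []
    for _, g in genes.iterrows():
        lg = str(g["lg"])
        tree = island_trees.get(lg)
        if tree is None:
            continue
        hits = tree.overlap(int(g["start"]), int(g["end"]))
        if not hits:
            continue
        pos = snp_pos.get(lg)
        if pos is None:
            continue
        # gene interval is half-open [start, end); SNP pos is 1-based, so the
        # covered 1-based positions are start+1 .. end
        lo = np.searchsorted(pos, int(g["start"]) + 1, side="left")
        hi = np.searchsorted(pos, int(g["end"]), side="right")
        if hi <= lo:
            continue
        fst_vals = snp_fst[lg][lo:hi]
        fst_vals = fst_vals[~np.isnan(fst_vals)]
        if fst_vals.size == 0:
            continue
        records.append(
            GeneRecord(
                gene=str(g["gene"]),
                lg=lg,
                start=int(g["start"]),
                end=int(g["end"]),
                n_snps=int(fst_vals.size),
                mean_fst=float(fst_vals.mean()),
                island_ids=tuple(sorted(h.data for h in hits)),
            )
        )
    records.sort(key=lambda r: (r.lg, r.start, r.gene))
    return records


def gene_records_table(records: list[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "lg": r.lg,
                "start": r.start,
                "end": r.end,
                "n_snps": r.n_snps,
                "mean_fst": r.mean_fst,
                "island_ids": ",".join(r.island_ids),
            }
            for r in records
        ]
    )
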