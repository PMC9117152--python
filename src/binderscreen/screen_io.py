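"""Shared data model and tabular/sequence IO for sorting screens.

The screen data model has three pieces: :class:`SortRecord` (one FACS sort's
metadata), :class:`PoolCounts` (per-design NGS counts for one sequenced pool)
and :class:`DesignCatalogue` (the ordered amino-acid sequences, in padded and
core form).  Counts and sort metadata travel as plain long-format TSV so that
files diff cleanly and other toolchains can produce them.

Design sequences are padded to a common length with a C-terminal (GGGS)n
linker before DNA synthesis; read matching therefore accepts either the
padded sequence or the core sequence followed by any run of GGGS repeats.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_LINKER_RE = re.compile(r"(GGGS)+$")

COUNTS_COLUMNS = ["pool_id", "design_id", "count"]
SORTS_COLUMNS = [
    "pool_id",
    "parent_pool_id",
    "concentration",
    "facs_collection_fraction",
    "cells_fed",
    "cells_collected_total",
    "avidity",
]


class FormatError(ValueError):
    """Raised for malformed input tables or catalogues."""


@dataclass(frozen=True)
class SortRecord:
    """Metadata for a single FACS sort.

    Parameters
    ----------
    pool_id:
        Identifier of the collected (child) pool this sort produced.
    parent_pool_id:
        Identifier of the pool fed to the sorter.
    concentration:
        Labelling target concentration in nM.  Zero is a valid
        (negative-control) concentration.
    facs_collection_fraction:
        Fraction of sorted cells that the machine collected, in (0, 1].
    cells_fed:
        Total cells fed to the sorter.
    cells_collected_total:
        Total cells collected across all designs.
    avidity:
        True when the sort used multivalent target-streptavidin labelling.
        Avidity sorts are never combined with monovalent ones downstream.
    """

    pool_id: str
    parent_pool_id: str
    concentration: float
    facs_collection_fraction: float
    cells_fed: float
    cells_collected_total: float
    avidity: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"negative concentration: {self.concentration}")
        if not (0 < self.facs_collection_fraction <= 1):
            raise ValueError(
                "facs_collection_fraction must be in (0, 1], got "
                f"{self.facs_collection_fraction}"
            )
        if self.cells_collected_total > self.cells_fed:
            raise ValueError("cells_collected_total exceeds cells_fed")


@dataclass
class PoolCounts:
    """Per-design NGS read counts for one pool."""

    pool_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for design_id, count in self.counts.items():
            if count < 0:
                raise FormatError(
                    f"negative count for design {design_id!r}: {count}"
                )

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def proportions(self) -> dict[str, float]:
        """Read-count proportions; empty dict for an empty pool."""
        total = self.total
        if total == 0:
            return {}
        return {d: c / total for d, c in self.counts.items()}

    def proportion(self, design_id: str) -> float:
        total = self.total
        if total == 0:
            return 0.0
        return self.counts.get(design_id, 0) / total


def strip_linker(sequence: str) -> str:
    """Remove a trailing (GGGS)n padding linker, if present."""
    return _LINKER_RE.sub("", sequence)


@dataclass
class DesignCatalogue:
    """Ordered design sequences, padded and core forms.

    ``sequences`` maps design_id to the padded amino-acid sequence (the form
    synthesized and sequenced).  Core sequences are derived by stripping any
    trailing (GGGS)n linker.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for design_id, seq in self.sequences.items():
            bad = set(seq) - set(AMINO_ACIDS)
            if bad:
                raise FormatError(
                    f"design {design_id!r} contains non-canonical residues: "
                    f"{sorted(bad)}"
                )
            if seq in seen:
                raise FormatError(
                    f"duplicate sequence shared by {seen[seq]!r} and "
                    f"{design_id!r}"
                )
            seen[seq] = design_id

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, design_id: str) -> bool:
        return design_id in self.sequences

    def core_sequences(self) -> dict[str, str]:
        return {d: strip_linker(s) for d, s in self.sequences.items()}


# ---------------------------------------------------------------------------
# Counts TSV


def read_counts(path) -> dict[str, PoolCounts]:
    """Read a long-format counts TSV (pool_id, design_id, count).

    Returns a mapping pool_id -> PoolCounts.  Raises :class:`FormatError`
    naming the offending line for malformed rows, negative counts or
    duplicated (pool, design) entries.
    """
    pools: dict[str, PoolCounts] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != COUNTS_COLUMNS:
            raise FormatError(
                f"{path}: expected header {COUNTS_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}: malformed row at line {lineno}")
            pool_id, design_id, raw = fields
            try:
                count = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer count at line {lineno}: {raw!r}"
                ) from None
            if count < 0:
                raise FormatError(
                    f"{path}: negative count at line {lineno}"
                )
            pool = pools.setdefault(pool_id, PoolCounts(pool_id, {}))
            if design_id in pool.counts:
                raise FormatError(
                    f"{path}: duplicate design {design_id!r} in pool "
                    f"{pool_id!r} at line {lineno}"
                )
            pool.counts[design_id] = count
    return pools


def write_counts(pools: Iterable[PoolCounts] | Mapping[str, PoolCounts], path) -> None:
    if isinstance(pools, Mapping):
        pools = pools.values()
    with open(path, "w") as fh:
        fh.write("\t".join(COUNTS_COLUMNS) + "\n")
        for pool in pools:
            for design_id in sorted(pool.counts):
                fh.write(f"{pool.pool_id}\t{design_id}\t{pool.counts[design_id]}\n")


# ---------------------------------------------------------------------------
# Sort metadata TSV


def read_sorts(path) -> dict[str, SortRecord]:
    """Read sort metadata TSV; validates parent-pool references."""
    df = pd.read_csv(path, sep="\t", dtype={"pool_id": str, "parent_pool_id": str})
    missing = set(SORTS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    sorts: dict[str, SortRecord] = {}
    for _, row in df.iterrows():
        rec = SortRecord(
            pool_id=row["pool_id"],
            parent_pool_id=row["parent_pool_id"],
            concentration=float(row["concentration"]),
            facs_collection_fraction=float(row["facs_collection_fraction"]),
            cells_fed=float(row["cells_fed"]),
            cells_collected_total=float(row["cells_collected_total"]),
            avidity=bool(row["avidity"]),
        )
        if rec.pool_id in sorts:
            raise FormatError(f"{path}: duplicate pool_id {rec.pool_id!r}")
        sorts[rec.pool_id] = rec
    # parent pools need no sort record of their own (the naive library is a
    # valid root); chain structure is validated where estimation needs it
    return sorts


def write_sorts(sorts: Iterable[SortRecord] | Mapping[str, SortRecord], path) -> None:
    if isinstance(sorts, Mapping):
        sorts = sorts.values()
    rows = [
        {
            "pool_id": s.pool_id,
            "parent_pool_id": s.parent_pool_id,
            "concentration": s.concentration,
            "facs_collection_fraction": s.facs_collection_fraction,
            "cells_fed": s.cells_fed,
            "cells_collected_total": s.cells_collected_total,
            "avidity": s.avidity,
        }
        for s in sorts
    ]
    pd.DataFrame(rows, columns=SORTS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Catalogue FASTA


def read_catalogue(path) -> DesignCatalogue:
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate design id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return DesignCatalogue(sequences)


def write_catalogue(catalogue: DesignCatalogue, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=design_id, description="")
        for design_id, seq in catalogue.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Read matching


def match_reads(
    reads: Iterable[str], catalogue: DesignCatalogue, pool_id: str = "pool"
) -> tuple[PoolCounts, int]:
    """Match translated reads against the catalogue.

    A read matches a design when it equals the padded sequence exactly, or
    equals the core sequence after stripping a trailing (GGGS)n run from the
    read.  Each read is counted at most once; catalogue uniqueness makes ties
    impossible.  Returns the pool counts and the number of unmatched reads.
    """
    padded_index = {seq: d for d, seq in catalogue.sequences.items()}
    core_index: dict[str, str] = {}
    for design_id, core in catalogue.core_sequences().items():
        if core in core_index:
            raise FormatError(
                f"duplicate core sequence shared by {core_index[core]!r} and "
                f"{design_id!r}"
            )
        core_index[core] = design_id

    counts: dict[str, int] = {}
    unmatched = 0
    for read in reads:
        read = read.upper()
        design_id = padded_index.get(read)
        if design_id is None:
            design_id = core_index.get(strip_linker(read))
        if design_id is None:
            unmatched += 1
        else:
            counts[design_id] = counts.get(design_id, 0) + 1
    return PoolCounts(pool_id, counts), unmatched
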