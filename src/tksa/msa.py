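"""Homolog alignment handling for the conservation filter.

The third selection criterion asks whether a proposed substitution is
already realized somewhere among homologs: a target residue observed at
the aligned column in at least ``min_count`` homolog sequences counts as
evolutionary support for the substitution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO


@dataclass
class Alignment:
    names: list[str]
    rows: list[str]  # equal-length gapped sequences, uppercase
    query_index: int = 0

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        length = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            if len(row) != length:
                raise ValueError(f"ragged alignment: row {name!r} has length "
                                 f"{len(row)}, expected {length}")
        if not 0 <= self.query_index < len(self.rows):
            raise ValueError("query_index out of range")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def query(self) -> str:
        return self.rows[self.query_index]

    def query_ungapped(self) -> str:
        return self.query.replace("-", "")


@dataclass
class ColumnProfile:
    """Residue composition of one alignment column over the homolog rows."""

    column: int  # 1-based
    counts: dict[str, int]  # non-gap residues only, query row excluded
    frequency: dict[str, float]
    n_homologs: int

    @property
    def has_coverage(self) -> bool:
        return sum(self.counts.values()) > 0


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "C").replace(".", "-")


def read_alignment(path: str | Path, format: str = "fasta",
                   query_index: int = 0) -> Alignment:
    """Read a FASTA or Clustal alignment; rows are uppercased and validated."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        bio_aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"{path}: cannot parse as {format}: {exc}") from exc
    names = [rec.id for rec in bio_aln]
    rows = [_normalize(str(rec.seq)) for rec in bio_aln]
    return Alignment(names=names, rows=rows, query_index=query_index)


def map_columns(alignment: Alignment, structure_sequence: str,
                offset: int = 1) -> dict[int, int]:
    """Bijection from structure residue numbers to 1-based query columns.

    Residue ``offset`` maps to the first non-gap query column, and so on.
    Raises on the first mismatch between the ungapped query and the
    structure-derived sequence.
    """
    ungapped = alignment.query_ungapped()
    if len(ungapped) != len(structure_sequence):
        raise ValueError(
            f"query has {len(ungapped)} residues but structure has "
            f"{len(structure_sequence)}")
    for i, (q, s) in enumerate(zip(ungapped, structure_sequence.upper())):
        if q != s and s != "X":
            raise ValueError(
                f"sequence mismatch at ungapped position {i + 1}: "
                f"query {q!r} vs structure {s!r}")
    mapping: dict[int, int] = {}
    residue = offset
    for col, symbol in enumerate(alignment.query, start=1):
        if symbol != "-":
            mapping[residue] = col
            residue += 1
    return mapping


def column_profile(alignment: Alignment, column: int) -> ColumnProfile:
    """Composition of 1-based ``column`` over homolog rows (query excluded)."""
    if not 1 <= column <= alignment.length:
        raise ValueError(f"column {column} outside alignment of length {alignment.length}")
    counts: dict[str, int] = {}
    n_homologs = 0
    for i, row in enumerate(alignment.rows):
        if i == alignment.query_index:
            continue
        n_homologs += 1
        symbol = row[column - 1]
        if symbol != "-":
            counts[symbol] = counts.get(symbol, 0) + 1
    total = sum(counts.values())
    frequency = {res: c / total for res, c in counts.items()} if total else {}
    return ColumnProfile(column=column, counts=counts, frequency=frequency,
                         n_homologs=n_homologs)


def substitution_supported(profile: ColumnProfile, target_residue: str,
                           min_count: int = 1) -> tuple[bool, float]:
    """Is the target residue seen in >= min_count homologs at this column?

    Returns ``(supported, frequency)``; an all-gap column is never
    supported (no homolog coverage) and has frequency 0.
    """
    target = target_residue.upper()
    if not profile.has_coverage:
        return False, 0.0
    count = profile.counts.get(target, 0)
    return count >= min_count, profile.frequency.get(target, 0.0)
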