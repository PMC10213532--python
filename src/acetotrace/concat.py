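"""Concatenated protein queries and the subquery coordinate registry.

Translated homology searches against whole-genome databases are convenient
to run with a single concatenated query: up to ~17 protein subqueries are
joined by spacers of 100 lowercase ``x`` letters.  Every downstream step
(per-subquery identity/coverage cut-offs, co-location analysis) needs to map
coordinates on the concatenated query back to the subquery they fall in;
this module owns that registry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_SPACER_LENGTH = 100
DEFAULT_SPACER_SYMBOL = "x"
DEFAULT_MAX_SUBQUERIES = 17


@dataclass(frozen=True)
class SubqueryInterval:
    """1-based inclusive interval of one subquery on the concatenated query."""

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SubqueryMap:
    """A concatenated query plus the coordinate registry of its subqueries.

    Attributes
    ----------
    concatenated_sequence:
        Subquery sequences joined by ``spacer_length`` copies of
        ``spacer_symbol``.
    intervals:
        Ordered, disjoint :class:`SubqueryInterval` records, separated by
        exactly ``spacer_length`` positions.
    """

    concatenated_sequence: str
    intervals: list[SubqueryInterval]
    spacer_length: int = DEFAULT_SPACER_LENGTH
    spacer_symbol: str = DEFAULT_SPACER_SYMBOL
    subquery_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subquery_lengths:
            self.subquery_lengths = {iv.name: iv.length for iv in self.intervals}

    @property
    def length(self) -> int:
        return len(self.concatenated_sequence)

    @property
    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    def interval_of(self, name: str) -> SubqueryInterval:
        for iv in self.intervals:
            if iv.name == name:
                return iv
        raise KeyError(f"unknown subquery: {name!r}")

    def subquery_sequence(self, name: str) -> str:
        iv = self.interval_of(name)
        return self.concatenated_sequence[iv.start - 1 : iv.end]


def build_concatenated_query(
    subqueries: Sequence[tuple[str, str]],
    spacer_length: int = DEFAULT_SPACER_LENGTH,
    spacer_symbol: str = DEFAULT_SPACER_SYMBOL,
    max_subqueries: int = DEFAULT_MAX_SUBQUERIES,
) -> SubqueryMap:
    """Join subqueries with spacers and record each one's coordinates.

    Subquery *i* (0-based) starts at ``1 + sum_{j<i}(len_j + spacer_length)``;
    the total length is ``sum(len) + spacer_length * (n - 1)``.

    Raises
    ------
    ValueError
        On duplicate names, empty sequences, or a sequence containing the
        reserved spacer symbol.  Exceeding ``max_subqueries`` only warns: the
        cap is a convention, not a hard limit.
    """
    if not subqueries:
        raise ValueError("at least one subquery is required")
    names = [name for name, _ in subqueries]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate subquery names: {dupes}")
    for name, seq in subqueries:
        if not seq:
            raise ValueError(f"empty sequence for subquery {name!r}")
        if spacer_symbol in seq:
            raise ValueError(
                f"subquery {name!r} contains the reserved spacer symbol "
                f"{spacer_symbol!r}"
            )
    if len(subqueries) > max_subqueries:
        warnings.warn(
            f"{len(subqueries)} subqueries exceeds the usual maximum of "
            f"{max_subqueries}",
            stacklevel=2,
        )

    spacer = spacer_symbol * spacer_length
    parts: list[str] = []
    intervals: list[SubqueryInterval] = []
    pos = 1
    for i, (name, seq) in enumerate(subqueries):
        if i > 0:
            parts.append(spacer)
            pos += spacer_length
        parts.append(seq)
        intervals.append(SubqueryInterval(name, pos, pos + len(seq) - 1))
        pos += len(seq)
    return SubqueryMap(
        concatenated_sequence="".join(parts),
        intervals=intervals,
        spacer_length=spacer_length,
        spacer_symbol=spacer_symbol,
    )


def locate(
    submap: SubqueryMap, qstart: int, qend: int
) -> list[tuple[str, int, int]]:
    """Assign a concatenated-query range to the subqueries it overlaps.

    Returns ``(name, overlap_start, overlap_end)`` for every subquery
    interval overlapping ``[qstart, qend]``, clipped to the subquery, in
    registry order.  A range falling entirely within spacer sequence yields
    an empty list.
    """
    if not (1 <= qstart <= qend <= submap.length):
        raise ValueError(
            f"coordinates ({qstart}, {qend}) out of range 1..{submap.length}"
        )
    out: list[tuple[str, int, int]] = []
    for iv in submap.intervals:
        lo = max(qstart, iv.start)
        hi = min(qend, iv.end)
        if lo <= hi:
            out.append((iv.name, lo, hi))
    return out


def read_subquery_panel(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein subquery panel from FASTA (record id = subquery name)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [(rec.id, str(rec.seq)) for rec in records]


def write_concatenated_query(
    submap: SubqueryMap, fasta_path: str | Path, intervals_path: str | Path,
    name: str = "concatenated_query",
) -> None:
    """Write the concatenated query FASTA plus a sidecar TSV of intervals."""
    rec = SeqRecord(Seq(submap.concatenated_sequence), id=name, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(intervals_path, "w") as fh:
        fh.write("subquery\tstart\tend\tlength\n")
        for iv in submap.intervals:
            fh.write(f"{iv.name}\t{iv.start}\t{iv.end}\t{iv.length}\n")


def read_interval_table(path: str | Path) -> list[SubqueryInterval]:
    intervals = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("subquery\t"):
            raise ValueError(f"unexpected interval-table header in {path}")
        for line in fh:
            name, start, end, _length = line.rstrip("\n").split("\t")
            intervals.append(SubqueryInterval(name, int(start), int(end)))
    return intervals
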