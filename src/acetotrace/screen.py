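"""Screen translated homology-search hits with per-subquery cut-offs.

The search output dialect is the common 12-column tabular layout extended
with the aligned sequence strings (``qseq``/``sseq``), i.e. the columns
``qseqid sseqid pident length qstart qend sstart send evalue bitscore qseq
sseq``.  Query coordinates live on the concatenated query; subject
coordinates are nucleotide positions on the genome, with ``sstart > send``
encoding the minus strand.

Screening proceeds in three steps:

1. each alignment (HSP) is split at spacer boundaries and assigned to the
   subqueries it overlaps (spacer columns are artificial sequence and are
   excluded from identity and coverage);
2. same-strand HSP segments on one replicon are merged into gene loci when
   their subject intervals lie within 300 bp of each other;
3. a locus passes for a subquery iff the best segment's identity meets the
   identity cut-off (default 25%), the union of segments covers enough of
   the subquery (default 80%), and, where a motif rule applies (the Ech
   catalytic subunit EchE: identity 28%, two CxxC nickel-binding motifs),
   the subject translation carries the required motif count.  All
   thresholds are inclusive minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .concat import SubqueryMap, locate

DEFAULT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "qstart", "qend",
    "sstart", "send", "evalue", "bitscore", "qseq", "sseq",
)
REQUIRED_COLUMNS = frozenset(
    {"sseqid", "qstart", "qend", "sstart", "send", "bitscore", "qseq", "sseq"}
)

# Same-strand HSP subject intervals closer than this are one gene locus.
LOCUS_MERGE_BP = 300

GAP = "-"


class SearchFormatError(ValueError):
    """Raised when tabular search output does not match the declared dialect."""


@dataclass
class HitRecord:
    """One local alignment between the concatenated query and a genomic locus."""

    genome_id: str
    contig_id: str
    qstart: int
    qend: int
    sstart: int
    send: int
    bitscore: float
    evalue: float
    aligned_query: str
    aligned_subject: str

    @property
    def minus_strand(self) -> bool:
        return self.sstart > self.send

    @property
    def strand(self) -> str:
        return "-" if self.minus_strand else "+"


@dataclass
class ScreenedHit:
    """Screening verdict for one (gene locus, subquery) pair."""

    genome_id: str
    contig_id: str
    subquery_name: str
    start: int              # forward-strand-normalized locus interval
    end: int
    strand: str
    identity_pct: float
    coverage_pct: float
    motif_count: int | None
    passed: bool
    fail_reason: str        # identity | coverage | motif | none
    bitscore: float
    subject_protein: str    # ungapped translation of the best segment
    source: HitRecord | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class ScreenRule:
    identity_cutoff: float = 25.0
    coverage_cutoff: float = 80.0
    motif_required: int | None = None


@dataclass
class ScreenRules:
    """Default cut-offs plus per-subquery overrides."""

    default: ScreenRule = field(default_factory=ScreenRule)
    per_subquery: dict[str, ScreenRule] = field(default_factory=dict)

    def for_subquery(self, name: str) -> ScreenRule:
        return self.per_subquery.get(name, self.default)


def default_rules(
    eche_subqueries: Iterable[str] = (),
    identity_cutoff: float = 25.0,
    coverage_cutoff: float = 80.0,
    eche_identity_cutoff: float = 28.0,
    eche_motifs_required: int = 2,
) -> ScreenRules:
    """The study's standard cut-offs: 25%/80%, with the stricter EchE rule
    (28% identity and two CxxC motifs) for the named subqueries."""
    over = {
        name: ScreenRule(eche_identity_cutoff, coverage_cutoff, eche_motifs_required)
        for name in eche_subqueries
    }
    return ScreenRules(ScreenRule(identity_cutoff, coverage_cutoff), over)


def parse_search_output(
    source: str | Path | TextIO,
    columns: Sequence[str] = DEFAULT_COLUMNS,
    genome_contig_sep: str = "|",
) -> list[HitRecord]:
    """Parse tabular translated-search output into :class:`HitRecord` rows.

    ``sseqid`` is split into ``genome_id`` and ``contig_id`` at
    ``genome_contig_sep``; a bare contig id is used for both.  Malformed rows
    raise :class:`SearchFormatError` naming the offending line numbers.
    """
    missing = REQUIRED_COLUMNS - set(columns)
    if missing:
        raise SearchFormatError(
            f"declared column order lacks required fields: {sorted(missing)}"
        )
    idx = {name: i for i, name in enumerate(columns)}

    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()

    records: list[HitRecord] = []
    bad: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < len(columns):
            bad.append((lineno, f"expected {len(columns)} columns, got {len(fields)}"))
            continue
        try:
            sseqid = fields[idx["sseqid"]]
            if genome_contig_sep in sseqid:
                genome_id, contig_id = sseqid.split(genome_contig_sep, 1)
            else:
                genome_id = contig_id = sseqid
            rec = HitRecord(
                genome_id=genome_id,
                contig_id=contig_id,
                qstart=int(fields[idx["qstart"]]),
                qend=int(fields[idx["qend"]]),
                sstart=int(fields[idx["sstart"]]),
                send=int(fields[idx["send"]]),
                bitscore=float(fields[idx["bitscore"]]),
                evalue=float(fields[idx["evalue"]]) if "evalue" in idx else 0.0,
                aligned_query=fields[idx["qseq"]],
                aligned_subject=fields[idx["sseq"]],
            )
        except ValueError as exc:
            bad.append((lineno, str(exc)))
            continue
        if len(rec.aligned_query) != len(rec.aligned_subject):
            bad.append((lineno, "aligned_query and aligned_subject differ in length"))
            continue
        records.append(rec)
    if bad:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad)
        raise SearchFormatError(f"malformed rows: {detail}")
    return records


def per_subquery_identity(aligned_query: str, aligned_subject: str) -> float:
    """Percent identity over all alignment columns, gap columns included.

    Case-insensitive; a gap never matches anything (including another gap).
    """
    if len(aligned_query) != len(aligned_subject):
        raise ValueError("aligned strings differ in length")
    if not aligned_query:
        return 0.0
    q = aligned_query.upper()
    s = aligned_subject.upper()
    matches = sum(
        1 for a, b in zip(q, s) if a == b and a != GAP
    )
    return 100.0 * matches / len(q)


def per_subquery_coverage(
    hsps: Iterable[tuple[int, int]], subquery_length: int
) -> float:
    """Percent of subquery positions covered by the union of HSP intervals."""
    covered = 0
    prev_end = 0
    for start, end in sorted(hsps):
        if not (1 <= start <= end <= subquery_length):
            raise ValueError(
                f"interval ({start}, {end}) outside 1..{subquery_length}"
            )
        lo = max(start, prev_end + 1)
        if end >= lo:
            covered += end - lo + 1
            prev_end = end
        prev_end = max(prev_end, end)
    return 100.0 * covered / subquery_length


def count_cxxc_motifs(protein: str) -> int:
    """Count CxxC motifs (cysteines three residues apart); overlaps count."""
    p = protein.upper()
    return sum(1 for i in range(len(p) - 3) if p[i] == "C" and p[i + 3] == "C")


@dataclass
class _Segment:
    """One HSP restricted to the columns assigned to a single subquery."""

    hit: HitRecord
    subquery_name: str
    q_local_start: int      # 1-based on the subquery
    q_local_end: int
    s_min: int              # genomic, forward-normalized
    s_max: int
    aligned_query: str
    aligned_subject: str

    @property
    def identity(self) -> float:
        return per_subquery_identity(self.aligned_query, self.aligned_subject)


def split_hit_by_subquery(hit: HitRecord, submap: SubqueryMap) -> list[_Segment]:
    """Split an HSP at spacer boundaries, dropping spacer columns.

    Walks the alignment column by column, tracking the query position (query
    gaps do not advance it) and the genomic codon interval of each subject
    residue, and emits one segment per overlapped subquery.
    """
    overlaps = locate(submap, hit.qstart, hit.qend)
    if not overlaps:
        return []
    interval_of = {name: submap.interval_of(name) for name, _, _ in overlaps}
    owner: dict[int, str] = {}
    for name, lo, hi in overlaps:
        for pos in range(lo, hi + 1):
            owner[pos] = name

    cols: dict[str, list[tuple[str, str, int | None, tuple[int, int] | None]]] = {}
    qpos = hit.qstart - 1
    s_index = 0  # count of subject residues consumed
    for qc, sc in zip(hit.aligned_query, hit.aligned_subject):
        if qc != GAP:
            qpos += 1
        if sc != GAP:
            if hit.minus_strand:
                s_lo, s_hi = hit.sstart - 3 * s_index - 2, hit.sstart - 3 * s_index
            else:
                s_lo, s_hi = hit.sstart + 3 * s_index, hit.sstart + 3 * s_index + 2
            s_index += 1
            s_span: tuple[int, int] | None = (s_lo, s_hi)
        else:
            s_span = None
        name = owner.get(qpos)
        if name is None:
            continue  # spacer column: artificial sequence, excluded
        cols.setdefault(name, []).append((qc, sc, qpos if qc != GAP else None, s_span))

    segments: list[_Segment] = []
    for name, columns in cols.items():
        qpositions = [q for _, _, q, _ in columns if q is not None]
        spans = [sp for _, _, _, sp in columns if sp is not None]
        if not qpositions or not spans:
            continue
        iv = interval_of[name]
        segments.append(
            _Segment(
                hit=hit,
                subquery_name=name,
                q_local_start=min(qpositions) - iv.start + 1,
                q_local_end=max(qpositions) - iv.start + 1,
                s_min=min(lo for lo, _ in spans),
                s_max=max(hi for _, hi in spans),
                aligned_query="".join(c[0] for c in columns),
                aligned_subject="".join(c[1] for c in columns),
            )
        )
    segments.sort(key=lambda s: s.q_local_start)
    return segments


def _merge_into_loci(segments: list[_Segment]) -> list[list[_Segment]]:
    """Group same-strand segments on one replicon into gene loci
    (subject intervals separated by < LOCUS_MERGE_BP bp merge)."""
    loci: list[list[_Segment]] = []
    cur: list[_Segment] = []
    cur_max_end = None
    for seg in sorted(segments, key=lambda s: (s.s_min, s.s_max)):
        if cur and seg.s_min - cur_max_end < LOCUS_MERGE_BP:
            cur.append(seg)
            cur_max_end = max(cur_max_end, seg.s_max)
        else:
            if cur:
                loci.append(cur)
            cur = [seg]
            cur_max_end = seg.s_max
    if cur:
        loci.append(cur)
    return loci


def screen(
    hits: Sequence[HitRecord],
    submap: SubqueryMap,
    rules: ScreenRules | None = None,
) -> list[ScreenedHit]:
    """Apply the retention rules and return one verdict per (locus, subquery).

    Identity is taken from the best-scoring segment of the locus; coverage
    from the union of all its segments on that subquery; the motif count from
    the ungapped subject translation of the best segment.  Failures carry a
    ``fail_reason`` (checked in the order identity, coverage, motif).
    """
    if rules is None:
        rules = default_rules()
    known = set(submap.names)
    unknown = set(rules.per_subquery) - known
    if unknown:
        raise ValueError(
            f"rules reference subqueries absent from the query map: {sorted(unknown)}"
        )

    by_replicon: dict[tuple[str, str, str], list[_Segment]] = {}
    for hit in hits:
        for seg in split_hit_by_subquery(hit, submap):
            key = (hit.genome_id, hit.contig_id, hit.strand)
            by_replicon.setdefault(key, []).append(seg)

    screened: list[ScreenedHit] = []
    for (genome_id, contig_id, strand), segments in sorted(by_replicon.items()):
        for locus in _merge_into_loci(segments):
            by_subquery: dict[str, list[_Segment]] = {}
            for seg in locus:
                by_subquery.setdefault(seg.subquery_name, []).append(seg)
            for name, segs in sorted(by_subquery.items()):
                best = max(
                    segs, key=lambda s: (s.hit.bitscore, s.identity, -s.q_local_start)
                )
                identity = best.identity
                coverage = per_subquery_coverage(
                    [(s.q_local_start, s.q_local_end) for s in segs],
                    submap.subquery_lengths[name],
                )
                subject_protein = best.aligned_subject.replace(GAP, "").upper()
                rule = rules.for_subquery(name)
                motif_count = (
                    count_cxxc_motifs(subject_protein)
                    if rule.motif_required is not None
                    else None
                )
                if identity < rule.identity_cutoff:
                    fail = "identity"
                elif coverage < rule.coverage_cutoff:
                    fail = "coverage"
                elif (
                    rule.motif_required is not None
                    and motif_count < rule.motif_required
                ):
                    fail = "motif"
                else:
                    fail = "none"
                screened.append(
                    ScreenedHit(
                        genome_id=genome_id,
                        contig_id=contig_id,
                        subquery_name=name,
                        start=min(s.s_min for s in segs),
                        end=max(s.s_max for s in segs),
                        strand=strand,
                        identity_pct=identity,
                        coverage_pct=coverage,
                        motif_count=motif_count,
                        passed=fail == "none",
                        fail_reason=fail,
                        bitscore=best.hit.bitscore,
                        subject_protein=subject_protein,
                        source=best.hit,
                    )
                )
    screened.sort(
        key=lambda h: (h.genome_id, h.contig_id, h.start, h.subquery_name)
    )
    return screened


def dedup_exact(sequences: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop exact duplicates (100% identity collapse), keeping first seen.

    Comparison is case-normalized with gaps stripped; input order of first
    occurrences is preserved.
    """
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    for name, seq in sequences:
        key = seq.replace(GAP, "").upper()
        if key not in seen:
            seen.add(key)
            out.append((name, seq))
    return out


def screened_to_frame(screened: Sequence[ScreenedHit]) -> pd.DataFrame:
    """Tabular view of screening verdicts (for TSV export)."""
    return pd.DataFrame(
        [
            {
                "genome_id": h.genome_id,
                "contig_id": h.contig_id,
                "subquery": h.subquery_name,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "identity_pct": round(h.identity_pct, 2),
                "coverage_pct": round(h.coverage_pct, 2),
                "motif_count": "" if h.motif_count is None else h.motif_count,
                "passed": h.passed,
                "fail_reason": h.fail_reason,
            }
            for h in screened
        ],
        columns=[
            "genome_id", "contig_id", "subquery", "start", "end", "strand",
            "identity_pct", "coverage_pct", "motif_count", "passed", "fail_reason",
        ],
    )
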