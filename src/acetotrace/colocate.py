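"""Gene co-location analysis and taxonomy-annotated sequence extraction.

Retained hits on one replicon are grouped by intergenic distance
(single-linkage): the study's default window is 15 kb, with a second,
tighter 0.5 kb window flagging operon-like organization.  Extracted hit
sequences are named with the host genome's GTDB taxonomy string and a
genomic-context code, so that a protein tree built from them carries the
host phylogeny in its labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .screen import ScreenedHit, dedup_exact

DEFAULT_DISTANCE_KB = 15.0
TIGHT_DISTANCE_KB = 0.5

NAME_DELIMITER = "|"


@dataclass
class LocusCluster:
    """Retained hits on one replicon within the distance window."""

    genome_id: str
    contig_id: str
    members: list[ScreenedHit]          # sorted by normalized start
    spacing_class: str                  # "tight" or "default"

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return max(m.end for m in self.members)


@dataclass
class NamedSequence:
    name: str
    sequence: str


def cluster_by_distance(
    hits: Iterable[ScreenedHit], distance_kb: float = DEFAULT_DISTANCE_KB
) -> list[LocusCluster]:
    """Single-linkage grouping of retained hits per (genome, contig).

    Two genes join one cluster iff the end-to-start gap between them is at
    most ``distance_kb * 1000`` bp; overlapping genes (negative gap) always
    join.  Minus-strand intervals are already forward-normalized on
    :class:`ScreenedHit`.  Singletons form singleton clusters.
    """
    if distance_kb <= 0:
        raise ValueError("distance_kb must be positive")
    max_gap = distance_kb * 1000.0
    spacing_class = "tight" if distance_kb <= TIGHT_DISTANCE_KB else "default"

    by_replicon: dict[tuple[str, str], list[ScreenedHit]] = {}
    for h in hits:
        if not h.passed:
            continue
        by_replicon.setdefault((h.genome_id, h.contig_id), []).append(h)

    clusters: list[LocusCluster] = []
    for (genome_id, contig_id), replicon_hits in sorted(by_replicon.items()):
        replicon_hits.sort(key=lambda h: (h.start, h.end, h.subquery_name))
        current: list[ScreenedHit] = []
        current_end = None
        for h in replicon_hits:
            if current and h.start - current_end <= max_gap:
                current.append(h)
                current_end = max(current_end, h.end)
            else:
                if current:
                    clusters.append(
                        LocusCluster(genome_id, contig_id, current, spacing_class)
                    )
                current = [h]
                current_end = h.end
        if current:
            clusters.append(
                LocusCluster(genome_id, contig_id, current, spacing_class)
            )
    return clusters


def context_code(cluster: LocusCluster) -> str:
    """Deterministic genomic-context code: members in genomic order with
    strand signs, dot-joined (e.g. ``acsB+.acsC+.acsD-``)."""
    if not cluster.members:
        raise ValueError("empty cluster has no context")
    members = sorted(cluster.members, key=lambda h: (h.start, h.end, h.subquery_name))
    return ".".join(f"{m.subquery_name}{m.strand}" for m in members)


def extract_named_sequences(
    clusters: Sequence[LocusCluster],
    taxonomy: Mapping[str, str],
) -> list[NamedSequence]:
    """One record per retained hit, named
    ``taxonomy|genome|contig:start-end(strand)|context`` (whitespace -> '_'),
    carrying the ungapped subject translation.
    """
    missing = sorted(
        {c.genome_id for c in clusters} - set(taxonomy)
    )
    if missing:
        raise KeyError(f"genomes absent from taxonomy table: {missing}")
    out: list[NamedSequence] = []
    for cluster in clusters:
        code = context_code(cluster)
        tax = taxonomy[cluster.genome_id]
        for m in cluster.members:
            name = NAME_DELIMITER.join(
                [
                    tax,
                    cluster.genome_id,
                    f"{cluster.contig_id}:{m.start}-{m.end}({m.strand})",
                    code,
                ]
            )
            name = "_".join(name.split())
            out.append(NamedSequence(name=name, sequence=m.subject_protein))
    return out


def dedup_named_sequences(records: Sequence[NamedSequence]) -> list[NamedSequence]:
    """Collapse exact duplicates across genomes (100% identity collapse)."""
    kept = dedup_exact([(r.name, r.sequence) for r in records])
    return [NamedSequence(name, seq) for name, seq in kept]


def cooccurrence_report(
    hits: Sequence[ScreenedHit],
    subquery_names: Sequence[str],
    default_kb: float = DEFAULT_DISTANCE_KB,
    tight_kb: float = TIGHT_DISTANCE_KB,
) -> pd.DataFrame:
    """Per-genome co-location report.

    One row per genome with a presence flag per subquery and, for every
    unordered subquery pair with retained hits, flags for co-location at the
    default and at the tight distance.  Empty input yields an empty frame.
    """
    passed = [h for h in hits if h.passed]
    if not passed:
        return pd.DataFrame()
    genomes = sorted({h.genome_id for h in passed})
    clusters_default = cluster_by_distance(passed, default_kb)
    clusters_tight = cluster_by_distance(passed, tight_kb)

    def pair_sets(clusters: list[LocusCluster]) -> dict[str, set[tuple[str, str]]]:
        pairs: dict[str, set[tuple[str, str]]] = {g: set() for g in genomes}
        for c in clusters:
            names = sorted({m.subquery_name for m in c.members})
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    pairs[c.genome_id].add((a, b))
        return pairs

    default_pairs = pair_sets(clusters_default)
    tight_pairs = pair_sets(clusters_tight)

    rows = []
    for g in genomes:
        present = {h.subquery_name for h in passed if h.genome_id == g}
        row: dict[str, object] = {"genome_id": g}
        for name in subquery_names:
            row[f"has_{name}"] = name in present
        for i, a in enumerate(subquery_names):
            for b in subquery_names[i + 1 :]:
                key = tuple(sorted((a, b)))
                row[f"coloc_{key[0]}~{key[1]}"] = key in default_pairs[g]
                row[f"tight_{key[0]}~{key[1]}"] = key in tight_pairs[g]
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome_id")


def clusters_to_bed(clusters: Sequence[LocusCluster]) -> pd.DataFrame:
    """BED-like table (0-based half-open) of clusters for browser use."""
    rows = []
    for c in clusters:
        for m in c.members:
            rows.append(
                {
                    "contig": c.contig_id,
                    "start": m.start - 1,
                    "end": m.end,
                    "name": context_code(c),
                    "score": round(m.identity_pct, 1),
                    "strand": m.strand,
                }
            )
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "name", "score", "strand"]
    )


def write_fasta(records: Sequence[NamedSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.sequence}\n")


def read_taxonomy_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping genome_id to a GTDB taxonomy string."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "genome_id" not in df.columns or "taxonomy_string" not in df.columns:
        raise ValueError(
            f"taxonomy table {path} must have columns genome_id, taxonomy_string"
        )
    return dict(zip(df["genome_id"], df["taxonomy_string"]))
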