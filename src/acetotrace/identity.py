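"""Pairwise identity profiling and small genome statistics.

Percent identity here is the alignment-based quantity comparative
genomicists quote when they say two subunits are "80% identical": a global
alignment under BLOSUM62 with affine gaps (open 11, extend 1, the classic
translated-search defaults), identity = 100 x matches / alignment columns.
Nucleotide sequences (e.g. 16S rRNA genes) use megablast-like match/mismatch
scores instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # affine gap cost 11 + 1 per residue
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def _nucleotide_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -7.0
    aligner.extend_gap_score = -2.0
    return aligner


def global_percent_identity(
    a: str, b: str, moltype: str = "protein"
) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Symmetric, bounded in [0, 100], and 100 exactly iff the sequences are
    identical.  ``moltype`` selects the scoring scheme ("protein" or
    "nucleotide").
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if moltype == "protein":
        aligner = _protein_aligner()
    elif moltype == "nucleotide":
        aligner = _nucleotide_aligner()
    else:
        raise ValueError(f"unknown moltype: {moltype!r}")
    alignment = aligner.align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


@dataclass
class IdentityProfile:
    """Per-pair identities between homologous subunits of two gene clusters."""

    per_pair: dict[str, float]   # "nameA~nameB" -> identity
    min_pct: float
    max_pct: float


def cluster_identity_profile(
    pairing: Sequence[tuple[str, str, str, str]], moltype: str = "protein"
) -> IdentityProfile:
    """Identity of each homolog pair ``(name_a, seq_a, name_b, seq_b)``
    between two gene clusters, with the min and max over pairs — the numbers
    behind statements like "subunit identities are 70-92%"."""
    if not pairing:
        raise ValueError("pairing must be non-empty")
    per_pair = {
        f"{na}~{nb}": global_percent_identity(sa, sb, moltype=moltype)
        for na, sa, nb, sb in pairing
    }
    values = list(per_pair.values())
    return IdentityProfile(per_pair, min(values), max(values))


def all_pairs_min_identity(
    sequences: Sequence[str], moltype: str = "protein"
) -> float:
    """Minimum pairwise global identity over all unordered pairs."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    return min(
        global_percent_identity(a, b, moltype=moltype)
        for a, b in combinations(sequences, 2)
    )


def gc_content(sequence: str) -> float:
    """G+C fraction in mol%, to one decimal; N and other ambiguity symbols
    are excluded from both numerator and denominator.  Invariant under
    reverse complement."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T symbols")
    return round(100.0 * gc / acgt, 1)


def extract_features(
    source: str | Path | TextIO,
    feature_type: str | None = None,
    locus_tags: Iterable[str] | None = None,
    product_contains: str | None = None,
) -> list[tuple[str, str]]:
    """Pull named sequences out of GenBank flat files.

    CDS features yield the record's own ``/translation`` when present
    (bit-exact agreement with the deposited annotation), falling back to
    translating the feature location with table 11; RNA and other features
    yield the nucleotide subsequence.  Names carry the locus_tag (falling
    back to gene/product).  Requesting locus tags that do not exist raises a
    lookup error listing them.
    """
    handle = source if hasattr(source, "read") else str(source)
    wanted = set(locus_tags) if locus_tags is not None else None
    found: list[tuple[str, str]] = []
    seen_tags: set[str] = set()
    for record in SeqIO.parse(handle, "genbank"):
        for feat in record.features:
            if feature_type is not None and feat.type != feature_type:
                continue
            tag = feat.qualifiers.get("locus_tag", [None])[0]
            if wanted is not None and tag not in wanted:
                continue
            product = feat.qualifiers.get("product", [""])[0]
            if product_contains is not None and product_contains not in product:
                continue
            if feat.type == "CDS":
                translation = feat.qualifiers.get("translation", [None])[0]
                if translation is None:
                    translation = str(
                        feat.extract(record.seq).translate(table=11, to_stop=True)
                    )
                seq = translation
            else:
                seq = str(feat.extract(record.seq))
            name = tag or feat.qualifiers.get("gene", [product or feat.type])[0]
            if tag:
                seen_tags.add(tag)
            found.append((name, seq))
    if wanted is not None:
        missing = sorted(wanted - seen_tags)
        if missing:
            raise KeyError(f"locus tags not found: {missing}")
    return found
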