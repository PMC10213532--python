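"""Compare pipeline output against a planted truth (end-to-end validation)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .colocate import LocusCluster
from .screen import ScreenedHit
from .synthetic import PlantedTruth


@dataclass
class RecoveryMetrics:
    recall: float
    precision: float
    n_expected: int
    n_predicted: int


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den else 1.0


def screen_recovery(
    screened: Sequence[ScreenedHit], truth: PlantedTruth
) -> RecoveryMetrics:
    """Recall/precision of the retained-gene set against the planted truth.

    Genes are keyed by (genome, contig, subquery); the generator plants each
    subquery at most once per replicon.
    """
    expected = {
        (g.genome_id, g.contig_id, g.subquery_name)
        for g in truth.genes
        if g.expected_pass
    }
    predicted = {
        (h.genome_id, h.contig_id, h.subquery_name)
        for h in screened
        if h.passed
    }
    tp = len(expected & predicted)
    return RecoveryMetrics(
        recall=_safe_ratio(tp, len(expected)),
        precision=_safe_ratio(tp, len(predicted)),
        n_expected=len(expected),
        n_predicted=len(predicted),
    )


def cluster_recovery(
    clusters: Sequence[LocusCluster],
    truth: PlantedTruth,
    spacing_class: str = "default",
) -> RecoveryMetrics:
    """Exact-set recall/precision of recovered clusters vs planted clusters."""
    expected = {
        (c.genome_id, c.contig_id, c.members)
        for c in truth.expected_clusters
        if c.spacing_class == spacing_class
    }
    predicted = {
        (
            c.genome_id,
            c.contig_id,
            frozenset(m.subquery_name for m in c.members),
        )
        for c in clusters
    }
    tp = len(expected & predicted)
    return RecoveryMetrics(
        recall=_safe_ratio(tp, len(expected)),
        precision=_safe_ratio(tp, len(predicted)),
        n_expected=len(expected),
        n_predicted=len(predicted),
    )
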