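"""End-to-end orchestration: screen -> co-locate -> extract -> gain/loss.

The pipeline is deterministic given its inputs and seed; every output file
is listed in a manifest with a content checksum so that reruns can be
verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import colocate, concat, gainloss, screen
from .colocate import (
    DEFAULT_DISTANCE_KB,
    TIGHT_DISTANCE_KB,
    cluster_by_distance,
    clusters_to_bed,
    cooccurrence_report,
    dedup_named_sequences,
    extract_named_sequences,
    read_taxonomy_table,
    write_fasta,
)
from .concat import build_concatenated_query, read_subquery_panel
from .screen import default_rules, parse_search_output, screened_to_frame


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for error reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    panel_path: str
    search_output_path: str
    taxonomy_path: str
    output_dir: str
    identity_cutoff: float = 25.0
    coverage_cutoff: float = 80.0
    eche_subqueries: tuple[str, ...] = ("echE",)
    eche_identity_cutoff: float = 28.0
    eche_motifs_required: int = 2
    default_kb: float = DEFAULT_DISTANCE_KB
    tight_kb: float = TIGHT_DISTANCE_KB
    gain_penalty: float = 2.0
    loss_penalty: float = 1.0
    tree_path: str | None = None
    presence_matrix_path: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("identity_cutoff", "coverage_cutoff", "eche_identity_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} = {v} outside [0, 100]")
        for name in ("default_kb", "tight_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("panel_path", "search_output_path", "taxonomy_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "eche_subqueries" in data:
            data["eche_subqueries"] = tuple(data["eche_subqueries"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage and return the artifact manifest (path -> sha256).

    Writes: screened-hit TSV, co-location report TSV, cluster BED-like TSV,
    extracted and deduplicated FASTA, and (when a tree and presence matrix
    are configured) gain/loss event, branch-summary TSVs, plus the manifest
    itself as JSON.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _Ctx()

    with stage("concat"):
        panel = read_subquery_panel(config.panel_path)
        submap = build_concatenated_query(panel)

    with stage("screen"):
        hits = parse_search_output(config.search_output_path)
        rules = default_rules(
            eche_subqueries=[
                n for n in config.eche_subqueries if n in submap.names
            ],
            identity_cutoff=config.identity_cutoff,
            coverage_cutoff=config.coverage_cutoff,
            eche_identity_cutoff=config.eche_identity_cutoff,
            eche_motifs_required=config.eche_motifs_required,
        )
        screened = screen.screen(hits, submap, rules)
        path = outdir / "screened_hits.tsv"
        screened_to_frame(screened).to_csv(path, sep="\t", index=False)
        written.append(path)

    with stage("colocate"):
        retained = [h for h in screened if h.passed]
        clusters_default = cluster_by_distance(retained, config.default_kb)
        clusters_tight = cluster_by_distance(retained, config.tight_kb)
        report = cooccurrence_report(
            retained, submap.names, config.default_kb, config.tight_kb
        )
        path = outdir / "colocation_report.tsv"
        report.to_csv(path, sep="\t")
        written.append(path)
        path = outdir / "clusters.bed.tsv"
        clusters_to_bed(clusters_default).to_csv(
            path, sep="\t", index=False, header=False
        )
        written.append(path)

    with stage("extract"):
        taxonomy = read_taxonomy_table(config.taxonomy_path)
        named = extract_named_sequences(clusters_default, taxonomy)
        path = outdir / "extracted.faa"
        write_fasta(named, path)
        written.append(path)
        path = outdir / "extracted_dedup.faa"
        write_fasta(dedup_named_sequences(named), path)
        written.append(path)

    if config.tree_path and config.presence_matrix_path:
        with stage("gainloss"):
            tree = gainloss.load_tree(config.tree_path)
            matrix = gainloss.read_presence_matrix(config.presence_matrix_path)
            recon = gainloss.reconstruct(
                matrix, tree, config.gain_penalty, config.loss_penalty
            )
            path = outdir / "gainloss_events.tsv"
            recon.events.to_csv(path, sep="\t", index=False)
            written.append(path)
            path = outdir / "branch_summary.tsv"
            gainloss.branch_summary(recon).to_csv(path, sep="\t", index=False)
            written.append(path)

    manifest = {str(p.relative_to(outdir)): _sha256(p) for p in written}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
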