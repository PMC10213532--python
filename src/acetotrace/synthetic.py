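"""Mock genome databases with planted gene clusters and known truth.

Every downstream stage of the pipeline — screening, co-location, extraction,
gain/loss — is tested against databases generated here, so no download is
ever needed.  The generator emulates the shape of a representative-genome
database with GTDB-format taxonomy strings and plants:

* protein families at controlled percent identity to the queries
  (including decoys below the 25% identity cut-off),
* gene clusters at controlled intergenic spacings (sub-0.5 kb "tight",
  sub-15 kb "default", and >15 kb splits, mirroring the acsA gene that sits
  16.8 kb away from the Wood-Ljungdahl cluster),
* EchE-like sequences carrying 0, 1 or 2 CxxC nickel-binding motifs,
* truncated homologs that fail the 80% coverage requirement,

and emits simulated translated-search output consistent with the planted
truth.  Coding sequences are random-codon back-translations under the
bacterial codon table (translation table 11); translating any planted
interval recovers the protein exactly, on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .concat import SubqueryMap
from .screen import HitRecord, count_cxxc_motifs

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_GC = 0.40
DEFAULT_TABLE_ID = 11

TIGHT_BP = 500
DEFAULT_BP = 15_000

_table = CodonTable.unambiguous_dna_by_id[DEFAULT_TABLE_ID]
CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    CODONS_FOR.setdefault(aa, []).append(codon)


class GenerationError(ValueError):
    pass


@dataclass
class PlantedGene:
    """One gene planted in a mock genome, with its screening expectation."""

    genome_id: str
    contig_id: str
    subquery_name: str
    start: int                  # 1-based inclusive
    end: int
    strand: str                 # '+' or '-'
    target_identity: float
    protein: str
    realized_identity: float = 0.0
    expected_pass: bool = True
    fail_reason: str = "none"   # why expected_pass is False


@dataclass(frozen=True)
class ExpectedCluster:
    genome_id: str
    contig_id: str
    members: frozenset[str]     # subquery names
    spacing_class: str          # "tight" or "default"


@dataclass
class PlantedTruth:
    genes: list[PlantedGene] = field(default_factory=list)
    expected_clusters: list[ExpectedCluster] = field(default_factory=list)

    def passing(self) -> list[PlantedGene]:
        return [g for g in self.genes if g.expected_pass]


@dataclass
class MockDatabase:
    genomes: dict[str, dict[str, str]]   # genome_id -> contig_id -> sequence
    taxonomy: dict[str, str]             # genome_id -> GTDB string
    truth: PlantedTruth
    panel: list[tuple[str, str]]         # (subquery_name, query protein)


@dataclass
class DatabaseConfig:
    """Layout of the mock database (the study conditions, not a dial)."""

    n_genomes: int = 20
    gc: float = DEFAULT_GC
    decoy_identity: float = 20.0
    homolog_identity: float = 80.0
    eche_identity: float = 55.0
    low_coverage_fraction: float = 0.7
    distal_gap_bp: int = 16_800          # excluded at the 15 kb window
    included_gap_bp: int = 9_500         # included at the 15 kb window
    tight_gap_bp: int = 400              # within the 0.5 kb window
    split_gap_bp: int = 20_000


def validate_taxonomy_string(taxonomy: str) -> None:
    ranks = taxonomy.split(";")
    prefixes = ["d__", "p__", "c__", "o__", "f__", "g__", "s__"]
    if len(ranks) != 7 or any(
        not r.startswith(p) for r, p in zip(ranks, prefixes)
    ):
        raise ValueError(f"not a 7-rank GTDB taxonomy string: {taxonomy!r}")


def random_protein(length: int, rng: np.random.Generator, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def mutate_to_identity(protein: str, target_identity: float, seed: int) -> str:
    """Substitute residues to reach the target percent identity.

    The number of mismatches is ``round(L * (1 - target/100))``, positions
    are drawn without replacement, and every substitution is to a different
    standard amino acid (never a stop), so the realized identity is exact up
    to rounding (within +-2 points for proteins of ~25 residues or more).
    Deterministic per seed.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    if not 0.0 <= target_identity <= 100.0:
        raise ValueError(f"target_identity {target_identity} outside [0, 100]")
    rng = np.random.default_rng(seed)
    length = len(protein)
    n_mut = int(round(length * (1.0 - target_identity / 100.0)))
    positions = rng.choice(length, size=n_mut, replace=False)
    out = list(protein)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != out[pos].upper()]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def percent_identity_ungapped(a: str, b: str) -> float:
    """Identity of two equal-length ungapped sequences (matches / length)."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return 100.0 * sum(x == y for x, y in zip(a.upper(), b.upper())) / len(a)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous back-translation under the bacterial codon table."""
    codons = []
    for aa in protein.upper():
        options = CODONS_FOR.get(aa)
        if not options:
            raise GenerationError(f"cannot back-translate symbol {aa!r}")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def random_background(length: int, rng: np.random.Generator, gc: float = DEFAULT_GC) -> str:
    p_at = (1 - gc) / 2
    p_gc = gc / 2
    return "".join(
        rng.choice(list("ATGC"), size=length, p=[p_at, p_at, p_gc, p_gc])
    )


def expected_clusters_from_genes(
    genes: Sequence[PlantedGene],
    default_bp: int = DEFAULT_BP,
    tight_bp: int = TIGHT_BP,
) -> list[ExpectedCluster]:
    """Truth-side single-linkage clustering of the passing genes, using the
    same end-to-start gap convention as the pipeline."""
    out: list[ExpectedCluster] = []
    by_replicon: dict[tuple[str, str], list[PlantedGene]] = {}
    for g in genes:
        if g.expected_pass:
            by_replicon.setdefault((g.genome_id, g.contig_id), []).append(g)
    for (genome_id, contig_id), gs in sorted(by_replicon.items()):
        gs.sort(key=lambda g: g.start)
        for max_gap, cls in ((default_bp, "default"), (tight_bp, "tight")):
            current: list[PlantedGene] = []
            current_end = None
            groups: list[list[PlantedGene]] = []
            for g in gs:
                if current and g.start - current_end <= max_gap:
                    current.append(g)
                    current_end = max(current_end, g.end)
                else:
                    if current:
                        groups.append(current)
                    current = [g]
                    current_end = g.end
            if current:
                groups.append(current)
            for grp in groups:
                out.append(
                    ExpectedCluster(
                        genome_id,
                        contig_id,
                        frozenset(m.subquery_name for m in grp),
                        cls,
                    )
                )
    return out


def plant_genes(
    background_length: int,
    genes: Sequence[PlantedGene],
    seed: int,
    gc: float = DEFAULT_GC,
) -> tuple[str, PlantedTruth]:
    """Place coding sequences on a random background.

    Each gene's CDS is a random-codon back-translation of its protein at its
    1-based inclusive coordinates (reverse-complemented on the minus
    strand); intervals must fit and must not overlap.
    """
    rng = np.random.default_rng(seed)
    sequence = list(random_background(background_length, rng, gc))
    placed = sorted(genes, key=lambda g: g.start)
    prev_end = 0
    for gene in placed:
        expected_end = gene.start + 3 * len(gene.protein) - 1
        if gene.end != expected_end:
            raise GenerationError(
                f"{gene.subquery_name}: end {gene.end} inconsistent with "
                f"protein length (expected {expected_end})"
            )
        if gene.start < 1 or gene.end > background_length:
            raise GenerationError(
                f"{gene.subquery_name}: interval {gene.start}-{gene.end} "
                f"outside background of length {background_length}"
            )
        if gene.start <= prev_end:
            raise GenerationError(
                f"{gene.subquery_name}: interval overlaps previous gene"
            )
        prev_end = gene.end
        cds = back_translate(gene.protein, rng)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        sequence[gene.start - 1 : gene.end] = list(cds)
    truth = PlantedTruth(
        genes=list(placed),
        expected_clusters=expected_clusters_from_genes(placed),
    )
    return "".join(sequence), truth


def translate_interval(sequence: str, start: int, end: int, strand: str) -> str:
    """Translate a 1-based inclusive genomic interval (table 11)."""
    sub = Seq(sequence[start - 1 : end])
    if strand == "-":
        sub = sub.reverse_complement()
    return str(sub.translate(table=DEFAULT_TABLE_ID))


def default_panel(seed: int = 7) -> list[tuple[str, str]]:
    """A Wood-Ljungdahl-like subquery panel of random query proteins.

    The EchE query carries exactly two CxxC motifs (and no other cysteines),
    like the catalytic subunit of an energy-converting hydrogenase.
    """
    rng = np.random.default_rng(seed)
    lengths = {
        "acsA": 250, "acsB": 300, "acsC": 200, "acsD": 150, "acsE": 180,
        "fhs": 250, "metF": 160, "echE": 200, "hydA": 220, "hydB": 180,
    }
    panel = []
    for name, length in lengths.items():
        if name == "echE":
            seq = list(random_protein(length, rng, alphabet=AMINO_ACIDS.replace("C", "")))
            for pos in ECHE_MOTIF_POSITIONS:
                seq[pos] = "C"
                seq[pos + 3] = "C"
            panel.append((name, "".join(seq)))
        else:
            panel.append((name, random_protein(length, rng)))
    return panel


ECHE_MOTIF_POSITIONS = (30, 120)  # 0-based starts of the two CxxC motifs


def make_eche_variant(
    query: str, n_motifs: int, target_identity: float, seed: int
) -> str:
    """An EchE-like homolog carrying exactly ``n_motifs`` CxxC motifs.

    Mutations avoid the motif positions and never introduce cysteines, then
    the unwanted motifs are ablated (each ablation costs one extra
    mismatch).
    """
    if n_motifs not in (0, 1, 2):
        raise ValueError("n_motifs must be 0, 1 or 2")
    rng = np.random.default_rng(seed)
    length = len(query)
    protected = {p for pos in ECHE_MOTIF_POSITIONS for p in (pos, pos + 3)}
    n_mut = int(round(length * (1.0 - target_identity / 100.0)))
    candidates = [i for i in range(length) if i not in protected]
    positions = rng.choice(candidates, size=min(n_mut, len(candidates)), replace=False)
    out = list(query)
    alphabet = AMINO_ACIDS.replace("C", "")
    for pos in positions:
        choices = [a for a in alphabet if a != out[pos].upper()]
        out[pos] = choices[rng.integers(len(choices))]
    for pos in ECHE_MOTIF_POSITIONS[n_motifs:]:
        out[pos] = "A"   # ablate the leading cysteine of the motif
    variant = "".join(out)
    assert count_cxxc_motifs(variant) == n_motifs
    return variant


def _taxonomy_for(i: int) -> str:
    return (
        "d__Bacteria;p__Firmicutes_A;c__Thermoanaerobacteria;"
        "o__Thermoanaerobacterales;f__Thermoanaerobacteraceae;"
        f"g__Mockgenus_{i:02d};s__Mockgenus_{i:02d} mockspecies"
    )


def generate_database(
    config: DatabaseConfig | None = None, seed: int = 42
) -> MockDatabase:
    """Build the full mock database, reproducible per seed.

    Always includes: one genome with a complete co-located cluster plus an
    included (9.5 kb) and an excluded (16.8 kb) distal gene; one genome with
    the cluster split beyond 15 kb; one genome with a sub-cut-off identity
    decoy and a truncated low-coverage decoy; and EchE-like genes with 2, 1
    and 0 CxxC motifs.  Remaining genomes carry random gene subsets at
    30-90% identity; the last genome is empty (negative control).
    """
    if config is None:
        config = DatabaseConfig()
    if config.n_genomes < 7:
        raise GenerationError("n_genomes must be at least 7 for the fixed layouts")
    rng = np.random.default_rng(seed)
    panel = default_panel(seed=7)
    queries = dict(panel)

    genomes: dict[str, dict[str, str]] = {}
    taxonomy: dict[str, str] = {}
    all_genes: list[PlantedGene] = []

    def homolog(name: str, identity: float, sub_seed: int) -> tuple[str, float]:
        prot = mutate_to_identity(queries[name], identity, sub_seed)
        return prot, percent_identity_ungapped(prot, queries[name])

    def add_genome(
        genome_id: str, layout: list[tuple[str, str, int, str, float, str]]
    ) -> None:
        """layout rows: (subquery, protein, start, strand, realized_id, fail)."""
        genes = []
        for name, prot, start, strand, realized, fail in layout:
            genes.append(
                PlantedGene(
                    genome_id=genome_id,
                    contig_id="c1",
                    subquery_name=name,
                    start=start,
                    end=start + 3 * len(prot) - 1,
                    strand=strand,
                    target_identity=realized,
                    protein=prot,
                    realized_identity=realized,
                    expected_pass=fail == "none",
                    fail_reason=fail,
                )
            )
        length = (max(g.end for g in genes) if genes else 1000) + 1000
        seq, _ = plant_genes(length, genes, seed=int(rng.integers(2**31)), gc=config.gc)
        genomes[genome_id] = {"c1": seq}
        taxonomy[genome_id] = _taxonomy_for(len(taxonomy) + 1)
        all_genes.extend(genes)

    def sub_seed() -> int:
        return int(rng.integers(2**31))

    # G001: full cluster with a tight pair, an included 9.5 kb gene and an
    # excluded 16.8 kb distal gene (the acsA situation).
    layout = []
    pos = 1001
    p, r = homolog("acsA", config.homolog_identity, sub_seed())
    layout.append(("acsA", p, pos, "+", r, "none"))
    end = pos + 3 * len(p) - 1
    pos = end + config.distal_gap_bp
    order = [
        ("acsB", "+", config.tight_gap_bp),
        ("acsC", "+", 2000),
        ("acsD", "-", 3000),
        ("acsE", "+", config.included_gap_bp),
        ("fhs", "+", None),
    ]
    for (name, strand, gap) in order:
        p, r = homolog(name, config.homolog_identity, sub_seed())
        layout.append((name, p, pos, strand, r, "none"))
        end = pos + 3 * len(p) - 1
        if gap is not None:
            pos = end + gap
    add_genome("G001", layout)

    # G002: cluster split beyond the 15 kb window.
    layout = []
    pos = 501
    for name, gap in (("acsB", 1000), ("acsC", config.split_gap_bp), ("acsD", 1000), ("acsE", None)):
        p, r = homolog(name, config.homolog_identity, sub_seed())
        layout.append((name, p, pos, "+", r, "none"))
        end = pos + 3 * len(p) - 1
        if gap is not None:
            pos = end + gap
    add_genome("G002", layout)

    # G003: identity decoy and low-coverage (truncated) decoy, plus one
    # genuine singleton.
    layout = []
    p, r = homolog("acsB", config.decoy_identity, sub_seed())
    layout.append(("acsB", p, 601, "+", r, "identity"))
    full = queries["fhs"]
    prefix = full[: int(len(full) * config.low_coverage_fraction)]
    p = mutate_to_identity(prefix, config.homolog_identity, sub_seed())
    r = percent_identity_ungapped(p, prefix)
    layout.append(("fhs", p, 6001, "+", r, "coverage"))
    p, r = homolog("metF", 70.0, sub_seed())
    layout.append(("metF", p, 12_001, "-", r, "none"))
    add_genome("G003", layout)

    # G004-G006: EchE-like genes with 2, 1, 0 CxxC motifs.
    for genome_id, n_motifs in (("G004", 2), ("G005", 1), ("G006", 0)):
        variant = make_eche_variant(
            queries["echE"], n_motifs, config.eche_identity, sub_seed()
        )
        realized = percent_identity_ungapped(variant, queries["echE"])
        fail = "none" if n_motifs >= 2 else "motif"
        layout = [("echE", variant, 2001, "+", realized, fail)]
        if genome_id == "G004":
            p, r = homolog("hydA", config.homolog_identity, sub_seed())
            start = 2001 + 3 * len(variant) - 1 + 1500
            layout.append(("hydA", p, start, "+", r, "none"))
            end = start + 3 * len(p) - 1
            p, r = homolog("hydB", config.homolog_identity, sub_seed())
            layout.append(("hydB", p, end + 300, "-", r, "none"))
        add_genome(genome_id, layout)

    # Filler genomes with random gene subsets; the last genome is empty.
    names = list(queries)
    for i in range(7, config.n_genomes + 1):
        genome_id = f"G{i:03d}"
        if i == config.n_genomes:
            add_genome(genome_id, [])
            continue
        k = int(rng.integers(2, 5))
        chosen = sorted(rng.choice(names, size=k, replace=False))
        layout = []
        pos = 1001
        for name in chosen:
            identity = float(rng.uniform(30, 90))
            if name == "echE":
                prot = make_eche_variant(queries["echE"], 2, max(identity, 40.0), sub_seed())
                realized = percent_identity_ungapped(prot, queries["echE"])
            else:
                prot, realized = homolog(name, identity, sub_seed())
            strand = "+" if rng.random() < 0.5 else "-"
            fail = "none" if realized >= 25.0 else "identity"
            if name == "echE" and realized < 28.0:
                fail = "identity"
            layout.append((name, prot, pos, strand, realized, fail))
            end = pos + 3 * len(prot) - 1
            pos = end + int(rng.integers(800, 10_000))
        add_genome(genome_id, layout)

    truth = PlantedTruth(
        genes=all_genes,
        expected_clusters=expected_clusters_from_genes(all_genes),
    )
    return MockDatabase(genomes=genomes, taxonomy=taxonomy, truth=truth, panel=panel)


def simulate_search_output(
    truth: PlantedTruth, submap: SubqueryMap
) -> list[HitRecord]:
    """Translated-search records consistent with the planted truth.

    One record per planted gene: query coordinates inside the gene's
    subquery interval, subject coordinates equal to the planted coordinates
    (reversed on the minus strand), aligned strings whose recomputed
    identity equals the realized identity.
    """
    records: list[HitRecord] = []
    for gene in truth.genes:
        try:
            iv = submap.interval_of(gene.subquery_name)
        except KeyError as exc:
            raise KeyError(
                f"planted gene references unknown subquery "
                f"{gene.subquery_name!r}"
            ) from exc
        qstart = iv.start
        qend = iv.start + len(gene.protein) - 1
        if qend > iv.end:
            raise GenerationError(
                f"{gene.subquery_name}: planted protein longer than subquery"
            )
        aligned_query = submap.concatenated_sequence[qstart - 1 : qend]
        matches = sum(
            a == b for a, b in zip(aligned_query, gene.protein)
        )
        if gene.strand == "-":
            sstart, send = gene.end, gene.start
        else:
            sstart, send = gene.start, gene.end
        records.append(
            HitRecord(
                genome_id=gene.genome_id,
                contig_id=gene.contig_id,
                qstart=qstart,
                qend=qend,
                sstart=sstart,
                send=send,
                bitscore=round(2.0 * matches, 1),
                evalue=1e-30,
                aligned_query=aligned_query,
                aligned_subject=gene.protein,
            )
        )
    return records


def write_search_output(records: Sequence[HitRecord], path: str | Path) -> None:
    """Write records in the 12-column tabular dialect the parser reads."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        "concatenated_query",
                        f"{r.genome_id}|{r.contig_id}",
                        "0.0",
                        str(len(r.aligned_query)),
                        str(r.qstart),
                        str(r.qend),
                        str(r.sstart),
                        str(r.send),
                        f"{r.evalue:g}",
                        f"{r.bitscore:g}",
                        r.aligned_query,
                        r.aligned_subject,
                    ]
                )
                + "\n"
            )


def write_database(
    db: MockDatabase, outdir: str | Path, combined_fasta: bool = True
) -> dict[str, Path]:
    """Write genome FASTA (combined or per genome), taxonomy TSV, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if combined_fasta:
        fasta = outdir / "genomes.fasta"
        with open(fasta, "w") as fh:
            for genome_id in sorted(db.genomes):
                for contig_id in sorted(db.genomes[genome_id]):
                    fh.write(f">{genome_id}|{contig_id}\n")
                    fh.write(db.genomes[genome_id][contig_id] + "\n")
        paths["genomes"] = fasta
    else:
        for genome_id in sorted(db.genomes):
            fasta = outdir / f"{genome_id}.fasta"
            with open(fasta, "w") as fh:
                for contig_id in sorted(db.genomes[genome_id]):
                    fh.write(f">{genome_id}|{contig_id}\n")
                    fh.write(db.genomes[genome_id][contig_id] + "\n")
            paths[genome_id] = fasta
    tax = outdir / "taxonomy.tsv"
    with open(tax, "w") as fh:
        fh.write("genome_id\ttaxonomy_string\n")
        for genome_id in sorted(db.taxonomy):
            fh.write(f"{genome_id}\t{db.taxonomy[genome_id]}\n")
    paths["taxonomy"] = tax
    truth = outdir / "truth.tsv"
    truth_frame(db.truth).to_csv(truth, sep="\t", index=False)
    paths["truth"] = truth
    panel = outdir / "panel.fasta"
    with open(panel, "w") as fh:
        for name, seq in db.panel:
            fh.write(f">{name}\n{seq}\n")
    paths["panel"] = panel
    return paths


def truth_frame(truth: PlantedTruth) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": g.genome_id,
                "contig_id": g.contig_id,
                "subquery": g.subquery_name,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "realized_identity": round(g.realized_identity, 2),
                "expected_pass": g.expected_pass,
                "fail_reason": g.fail_reason,
            }
            for g in truth.genes
        ],
        columns=[
            "genome_id", "contig_id", "subquery", "start", "end", "strand",
            "realized_identity", "expected_pass", "fail_reason",
        ],
    )
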