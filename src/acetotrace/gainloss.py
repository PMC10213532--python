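"""Ancestral gene-content reconstruction and loss classification.

Given a rooted reference tree and a binary family-by-taxon presence matrix
(e.g. COG occurrence over a clade), asymmetric Wagner (Sankoff) parsimony
reconstructs per-branch gains and losses: each family's ancestral states
minimize ``gain_penalty * #gains + loss_penalty * #losses`` by dynamic
programming over the tree.  The default penalties (gain 2, loss 1) make
gains twice as expensive as losses, the usual prior for gene-content
evolution where independent acquisition is rarer than loss.

On top of the reconstruction, :func:`classify_focal_losses` reproduces the
unique-loss / paired-loss logic used to compare two focal taxa (e.g. the two
acetogens of a clade) against the remaining clade members: a *paired loss*
is a family lost independently on each focal lineage while retained in every
background taxon.

Ties in the dynamic programming are broken toward ancestral presence (i.e.
toward losses), and a root-state tie is resolved as present, so the
reconstruction is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

GAIN_PENALTY_DEFAULT = 2.0
LOSS_PENALTY_DEFAULT = 1.0


def load_tree(source: str | Path) -> dendropy.Tree:
    """Load a rooted Newick tree, labeling unlabeled internal nodes
    ``N1, N2, ...`` in preorder so every branch is addressable."""
    try:
        is_file = Path(str(source)).exists()
    except OSError:
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    tree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    label_internal_nodes(tree)
    return tree


def label_internal_nodes(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label is None or node.label == "":
            i += 1
            node.label = f"N{i}"


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label


@dataclass
class EventReconstruction:
    """Per-family ancestral states and per-branch events on a fixed tree.

    ``events`` has one row per (family, branch) with an event, where a
    branch is named by its child node; ``states`` maps family -> node label
    -> 0/1.
    """

    tree: dendropy.Tree
    states: dict[str, dict[str, int]]
    events: pd.DataFrame                # columns: family, branch, event
    penalties: dict[str, float]
    gain_penalty: float
    loss_penalty: float
    leaf_states: pd.DataFrame           # the input presence matrix

    @property
    def total_penalty(self) -> float:
        return float(sum(self.penalties.values()))

    def branch_labels(self) -> list[str]:
        return [
            _node_label(n)
            for n in self.tree.preorder_node_iter()
            if n.parent_node is not None
        ]

    def leafset_of_branch(self, branch: str) -> frozenset[str]:
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None and _node_label(node) == branch:
                return frozenset(
                    leaf.taxon.label for leaf in node.leaf_iter()
                )
        raise KeyError(f"unknown branch: {branch}")


def reconstruct(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    gain_penalty: float = GAIN_PENALTY_DEFAULT,
    loss_penalty: float = LOSS_PENALTY_DEFAULT,
) -> EventReconstruction:
    """Sankoff dynamic programming over the tree for every family.

    ``matrix`` is families x taxa with 0/1 entries; its column set must
    equal the tree's leaf set.  Returns states, events and the per-family
    minimal penalty.
    """
    if gain_penalty <= 0 or loss_penalty <= 0:
        raise ValueError("penalties must be positive")
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    taxa = set(map(str, matrix.columns))
    if leaves != taxa:
        raise ValueError(
            f"taxon mismatch: matrix-only={sorted(taxa - leaves)}, "
            f"tree-only={sorted(leaves - taxa)}"
        )
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence matrix entries must be 0 or 1")

    def trans(s: int, t: int) -> float:
        if s == t:
            return 0.0
        return gain_penalty if t == 1 else loss_penalty

    postorder = list(tree.postorder_node_iter())
    states: dict[str, dict[str, int]] = {}
    penalties: dict[str, float] = {}
    event_rows: list[dict[str, str]] = []

    for family in matrix.index:
        leaf_state = {
            str(c): int(matrix.at[family, c]) for c in matrix.columns
        }
        cost: dict[dendropy.Node, list[float]] = {}
        for node in postorder:
            if node.is_leaf():
                obs = leaf_state[node.taxon.label]
                cost[node] = [math.inf, math.inf]
                cost[node][obs] = 0.0
            else:
                c = [0.0, 0.0]
                for s in (0, 1):
                    for child in node.child_nodes():
                        c[s] += min(
                            trans(s, t) + cost[child][t] for t in (0, 1)
                        )
                cost[node] = c

        root = tree.seed_node
        # ties at the root resolve to presence
        root_state = 1 if cost[root][1] <= cost[root][0] else 0
        penalties[str(family)] = cost[root][root_state]

        fam_states: dict[str, int] = {}
        assign: dict[dendropy.Node, int] = {root: root_state}
        for node in tree.preorder_node_iter():
            s = assign[node]
            fam_states[_node_label(node)] = s
            for child in node.child_nodes():
                options = {t: trans(s, t) + cost[child][t] for t in (0, 1)}
                # tie toward ancestral presence
                child_state = 1 if options[1] <= options[0] else 0
                assign[child] = child_state
                if child_state != s:
                    event_rows.append(
                        {
                            "family": str(family),
                            "branch": _node_label(child),
                            "event": "gain" if child_state == 1 else "loss",
                        }
                    )
        states[str(family)] = fam_states

    events = pd.DataFrame(event_rows, columns=["family", "branch", "event"])
    return EventReconstruction(
        tree=tree,
        states=states,
        events=events,
        penalties=penalties,
        gain_penalty=gain_penalty,
        loss_penalty=loss_penalty,
        leaf_states=matrix.copy(),
    )


def classify_focal_losses(
    recon: EventReconstruction,
    focal_taxa: tuple[str, str],
    background_taxa: Iterable[str],
) -> pd.Series:
    """Label every family by its loss pattern over two focal taxa.

    * ``paired_loss`` — a loss event lies on branches covering each focal
      taxon separately (terminal branch, or ancestral to exactly one focal
      taxon and no background taxon) while the family is present in every
      background taxon: the loss happened in parallel in the two lineages.
    * ``unique_loss_A`` / ``unique_loss_B`` — the same, for exactly one
      focal taxon.
    * ``retained`` — present in both focal taxa and all background taxa.
    * ``other`` — anything else (e.g. background absences).
    """
    focal_a, focal_b = focal_taxa
    background = set(background_taxa)
    leaves = {leaf.taxon.label for leaf in recon.tree.leaf_node_iter()}
    for t in (focal_a, focal_b):
        if t not in leaves:
            raise ValueError(f"focal taxon {t!r} is not a leaf of the tree")
    absent_bg = background - leaves
    if absent_bg:
        raise ValueError(f"background taxa not in tree: {sorted(absent_bg)}")

    leafset = {
        br: recon.leafset_of_branch(br) for br in recon.branch_labels()
    }

    def focal_loss_branches(family: str) -> tuple[bool, bool]:
        fam_events = recon.events[
            (recon.events["family"] == family)
            & (recon.events["event"] == "loss")
        ]
        lost_a = lost_b = False
        for br in fam_events["branch"]:
            ls = leafset[br]
            if ls & background:
                continue
            has_a, has_b = focal_a in ls, focal_b in ls
            if has_a and not has_b:
                lost_a = True
            elif has_b and not has_a:
                lost_b = True
        return lost_a, lost_b

    labels: dict[str, str] = {}
    for family in recon.leaf_states.index:
        fam = str(family)
        row = recon.leaf_states.loc[family]
        bg_present = all(int(row[t]) == 1 for t in background)
        present_a = int(row[focal_a]) == 1
        present_b = int(row[focal_b]) == 1
        if bg_present:
            lost_a, lost_b = focal_loss_branches(fam)
            if lost_a and lost_b:
                labels[fam] = "paired_loss"
                continue
            if lost_a and not lost_b and present_b:
                labels[fam] = "unique_loss_A"
                continue
            if lost_b and not lost_a and present_a:
                labels[fam] = "unique_loss_B"
                continue
            if present_a and present_b:
                labels[fam] = "retained"
                continue
        labels[fam] = "other"
    return pd.Series(labels, name="loss_class")


def branch_summary(
    recon: EventReconstruction,
    categories: Mapping[str, str] | None = None,
    category_filter: str | None = None,
) -> pd.DataFrame:
    """Per-branch gain/loss counts, optionally restricted to one family
    category (e.g. "carbohydrate transport and metabolism")."""
    events = recon.events
    if category_filter is not None:
        if categories is None:
            raise ValueError("category_filter given without a category table")
        if category_filter not in set(categories.values()):
            raise ValueError(f"unknown category: {category_filter!r}")
        keep = {f for f, c in categories.items() if c == category_filter}
        events = events[events["family"].isin(keep)]
    rows = []
    for branch in recon.branch_labels():
        b = events[events["branch"] == branch]
        rows.append(
            {
                "branch": branch,
                "gains": int((b["event"] == "gain").sum()),
                "losses": int((b["event"] == "loss").sum()),
            }
        )
    return pd.DataFrame(rows, columns=["branch", "gains", "losses"])


def simulate_presence_matrix(
    tree: dendropy.Tree,
    n_families: int,
    loss_prob: float = 0.1,
    gain_prob: float = 0.02,
    seed: int = 0,
    root_present_prob: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve binary presence down the tree (present at the root by default,
    losing with ``loss_prob`` and regaining with ``gain_prob`` per branch).

    Returns the leaf presence matrix and the true per-branch event table —
    the ground truth for parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    rows = {}
    true_events = []
    for i in range(n_families):
        family = f"FAM{i:04d}"
        state = {tree.seed_node: int(rng.random() < root_present_prob)}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent = state[node.parent_node]
            s = parent
            if parent == 1 and rng.random() < loss_prob:
                s = 0
                true_events.append(
                    {"family": family, "branch": _node_label(node), "event": "loss"}
                )
            elif parent == 0 and rng.random() < gain_prob:
                s = 1
                true_events.append(
                    {"family": family, "branch": _node_label(node), "event": "gain"}
                )
            state[node] = s
        rows[family] = {
            leaf.taxon.label: state[leaf] for leaf in tree.leaf_node_iter()
        }
    matrix = pd.DataFrame.from_dict(rows, orient="index")[taxa]
    return matrix, pd.DataFrame(true_events, columns=["family", "branch", "event"])


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Families-in-rows, taxa-in-columns 0/1 TSV."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_category_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"category table {path} needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
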