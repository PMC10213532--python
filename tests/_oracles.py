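"""Independent oracles used by the test suite.

The brute-force parsimony score enumerates every internal labeling, so it is
exponential but exact; the random-tree builder produces rooted binary trees
from nested parenthesization, independent of the package's tree handling.
"""

import itertools
import math

import numpy as np


def brute_force_penalty(tree, leaf_state, gain_penalty, loss_penalty):
    """Minimum weighted event count over all internal-node labelings."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = math.inf
    for combo in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        cost = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            p = assign[node.parent_node]
            s = (
                leaf_state[node.taxon.label]
                if node.is_leaf()
                else assign[node]
            )
            if p == 0 and s == 1:
                cost += gain_penalty
            elif p == 1 and s == 0:
                cost += loss_penalty
        best = min(best, cost)
    return best


def random_binary_newick(taxa, rng):
    """A uniform-ish random rooted binary topology as a newick string."""
    def build(names):
        if len(names) == 1:
            return names[0]
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        return f"({build(left)},{build(right)})"

    names = list(taxa)
    rng.shuffle(names)
    return build(names) + ";"


def random_instance(rng, max_leaves=12):
    """A random (newick, leaf states, penalties) parsimony instance."""
    n = int(rng.integers(3, max_leaves + 1))
    taxa = [f"t{i}" for i in range(n)]
    newick = random_binary_newick(taxa, rng)
    states = {t: int(rng.integers(0, 2)) for t in taxa}
    gain = float(rng.uniform(0.5, 3.0))
    loss = float(rng.uniform(0.5, 3.0))
    return newick, taxa, states, gain, loss
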