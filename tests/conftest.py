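import itertools

import numpy as np
import pytest

from archaeostyle.parsimony import CharacterMatrix
from archaeostyle.trees import UnrootedTree


@pytest.fixture
def quartet_tree():
    """((A,B),(C,D)) as an unrooted tree on taxa 0..3."""
    t = UnrootedTree(4)
    edge = next(e for e in t.edges() if 2 in e)
    t.attach_leaf(3, edge)
    return t


def random_binary_matrix(rng, n_taxa, n_chars, n_states=2, missing_p=0.0):
    masks = (1 << rng.integers(0, n_states, (n_taxa, n_chars))).astype(np.int64)
    full = (1 << n_states) - 1
    if missing_p:
        miss = rng.random((n_taxa, n_chars)) < missing_p
        masks = np.where(miss, full, masks)
    return CharacterMatrix(
        tuple(f"T{i}" for i in range(n_taxa)), masks, "0123456789"[:n_states]
    )


def brute_force_steps(tree: UnrootedTree, matrix: CharacterMatrix) -> np.ndarray:
    """Minimum changes per character over all internal (and permitted leaf)
    state assignments — the exhaustive oracle for Fitch lengths."""
    k = len(matrix.symbols)
    internals = sorted(n for n in tree.adj if n >= tree.n_taxa)
    internal_edges = [(u, v) for u, v in tree.edges()
                      if u >= tree.n_taxa and v >= tree.n_taxa]
    leaf_parent = {leaf: next(iter(tree.adj[leaf])) for leaf in range(tree.n_taxa)}
    out = np.zeros(matrix.n_characters, dtype=int)
    for j in range(matrix.n_characters):
        cells = [int(matrix.masks[leaf, j]) for leaf in range(tree.n_taxa)]
        best = None
        for states in itertools.product(range(k), repeat=len(internals)):
            assign = dict(zip(internals, states))
            cost = sum(assign[u] != assign[v] for u, v in internal_edges)
            # a leaf is free iff its state set admits its neighbour's state
            cost += sum(
                0 if cells[leaf] >> assign[parent] & 1 else 1
                for leaf, parent in leaf_parent.items()
            )
            if best is None or cost < best:
                best = cost
        out[j] = best
    return out
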