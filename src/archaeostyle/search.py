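"""Heuristic parsimony search: random-addition starts, SPR hill-climbing,
the parsimony ratchet, and the support measures computed from its output.

The ratchet alternates branch swapping on a perturbed matrix (a random
quarter of the characters upweighted) with swapping on the original
weights, accepting any tree at least as short as the incumbent — the
standard device for escaping local optima in morphological parsimony.
Every local optimum visited is archived together with its length, so
near-optimal consensus trees and decay indices can be read back out of a
single search.  All randomness flows from one integer seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .parsimony import CharacterMatrix, fitch_length, fitch_steps
from .trees import UnrootedTree, all_topologies, strict_consensus


@dataclass
class SearchResult:
    """Outcome of a parsimony search.

    ``best_trees`` holds the distinct best topologies (compared as strict
    bipartition sets); ``archive`` maps each visited topology key to
    ``(length, tree)`` for every tree within ``archive_window`` steps of
    the best length seen.
    """

    best_length: int
    best_trees: list[UnrootedTree]
    per_char_steps: np.ndarray
    seed: int | None = None
    archive: dict = field(default_factory=dict)
    archive_window: int = 0
    iterations_run: int = 0
    log: list[str] = field(default_factory=list)

    def representative(self) -> UnrootedTree:
        return self.best_trees[0]

    def trees_within(self, extra_steps: int) -> list[UnrootedTree]:
        limit = self.best_length + extra_steps
        return [t for (length, t) in self.archive.values() if length <= limit]


# ---------------------------------------------------------------------------
# Greedy stepwise addition
# ---------------------------------------------------------------------------

def random_addition_start(matrix: CharacterMatrix, seed: int) -> UnrootedTree:
    """Greedy stepwise-addition tree from a seeded random taxon order."""
    n = matrix.n_taxa
    if n < 3:
        raise InvalidInputError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    # relabel so the first three drawn taxa form the base triplet
    tree = UnrootedTree(n, adj={n: {int(order[0]), int(order[1]), int(order[2])},
                                int(order[0]): {n}, int(order[1]): {n},
                                int(order[2]): {n}})
    sub = _submatrix(matrix, sorted(order[:3]))
    for k in range(3, n):
        leaf = int(order[k])
        present = sorted(int(x) for x in order[: k + 1])
        sub = _submatrix(matrix, present)
        best_len, best_tree = None, None
        for edge in tree.edges():
            cand = tree.copy()
            cand.attach_leaf(leaf, edge)
            length, _ = fitch_length(_relabel(cand, present), sub)
            if best_len is None or length < best_len:
                best_len, best_tree = length, cand
        tree = best_tree
    return tree


def _submatrix(matrix: CharacterMatrix, taxa_idx) -> CharacterMatrix:
    from dataclasses import replace

    return replace(
        matrix,
        taxa=tuple(matrix.taxa[i] for i in taxa_idx),
        masks=matrix.masks[list(taxa_idx)],
    )


def _relabel(tree: UnrootedTree, present: list[int]) -> UnrootedTree:
    """Compact a tree over a taxon subset onto indices 0..k-1."""
    remap = {orig: i for i, orig in enumerate(present)}
    k = len(present)
    out = UnrootedTree.__new__(UnrootedTree)
    out.n_taxa = k
    node_map = {}
    next_internal = [k]

    def mapped(u):
        if u not in node_map:
            if u in remap:
                node_map[u] = remap[u]
            else:
                node_map[u] = next_internal[0]
                next_internal[0] += 1
        return node_map[u]

    out.adj = {}
    for u, nbrs in tree.adj.items():
        mu = mapped(u)
        out.adj.setdefault(mu, set()).update(mapped(v) for v in nbrs)
    out._next_id = next_internal[0]
    return out


# ---------------------------------------------------------------------------
# SPR hill climbing
# ---------------------------------------------------------------------------

def spr_local_search(
    tree: UnrootedTree,
    matrix: CharacterMatrix,
    *,
    forbidden_clade: int | None = None,
    visit=None,
) -> tuple[UnrootedTree, int]:
    """First-improvement SPR descent to a local optimum.

    ``forbidden_clade`` (a bipartition mask) restricts the walk to trees
    *not* displaying that clade — the converse-constraint device used for
    decay indices.  ``visit(length, tree)`` is called on every evaluated
    candidate so callers can archive near-optimal trees.
    """
    current = tree
    cur_len, _ = fitch_length(current, matrix)
    if visit is not None:
        visit(cur_len, current)
    improved = True
    while improved:
        improved = False
        for cand in current.spr_neighbours():
            if forbidden_clade is not None and cand.contains_clade(forbidden_clade):
                continue
            length, _ = fitch_length(cand, matrix)
            if visit is not None:
                visit(length, cand)
            if length < cur_len:
                current, cur_len = cand, length
                improved = True
                break
    return current, cur_len


# ---------------------------------------------------------------------------
# The parsimony ratchet
# ---------------------------------------------------------------------------

def ratchet_search(
    matrix: CharacterMatrix,
    *,
    iterations: int = 50,
    perturb_fraction: float = 0.25,
    perturb_weight: int = 2,
    n_starts: int = 4,
    seed: int = 0,
    archive_window: int = 2,
    forbidden_clade: int | None = None,
) -> SearchResult:
    """Parsimony ratchet from multiple random-addition starts.

    Each iteration upweights a random ``perturb_fraction`` of the
    characters by ``perturb_weight``, swaps to a local optimum under the
    perturbed weights, restores the weights, swaps again, and accepts the
    result if it is no longer than the incumbent.  Distinct best topologies
    and all visited trees within ``archive_window`` of the best length are
    collected.  Fully reproducible from ``seed``.
    """
    if iterations < 1:
        raise InvalidInputError("iterations must be >= 1")
    if not 0.0 < perturb_fraction < 1.0:
        raise InvalidInputError("perturb_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_char = matrix.n_characters

    best_len = None
    best = {}
    archive = {}
    log = []

    def visit(length, tree):
        nonlocal best_len
        if best_len is None or length < best_len:
            best_len = length
            best.clear()
        if length == best_len:
            best.setdefault(tree.topology_key(), tree)

    def archive_visit(length, tree):
        visit(length, tree)
        if length <= (best_len + archive_window):
            key = tree.topology_key()
            old = archive.get(key)
            if old is None or length < old[0]:
                archive[key] = (length, tree)

    iters_done = 0
    for start in range(n_starts):
        start_seed = int(rng.integers(0, 2**31 - 1))
        tree = random_addition_start(matrix, seed=start_seed)
        if forbidden_clade is not None:
            tree = _break_clade(tree, forbidden_clade, matrix)
        tree, length = spr_local_search(
            tree, matrix, forbidden_clade=forbidden_clade, visit=archive_visit
        )
        log.append(f"start {start}: addition seed {start_seed}, local optimum {length}")
        for it in range(iterations):
            sel = rng.random(n_char) < perturb_fraction
            if not sel.any():
                sel[rng.integers(0, n_char)] = True
            w = matrix.weights.copy()
            w[sel] *= perturb_weight
            perturbed = matrix.reweighted(w)
            t_pert, _ = spr_local_search(
                tree, perturbed, forbidden_clade=forbidden_clade
            )
            t_new, len_new = spr_local_search(
                t_pert, matrix, forbidden_clade=forbidden_clade, visit=archive_visit
            )
            if len_new <= length:
                tree, length = t_new, len_new
            iters_done += 1
        log.append(f"start {start}: final length {length}")

    # prune the archive to the final window
    limit = best_len + archive_window
    archive = {k: v for k, v in archive.items() if v[0] <= limit}
    trees = list(best.values())
    steps = fitch_steps(trees[0], matrix)
    return SearchResult(
        best_length=int(best_len),
        best_trees=trees,
        per_char_steps=steps,
        seed=seed,
        archive=archive,
        archive_window=archive_window,
        iterations_run=iters_done,
        log=log,
    )


def _break_clade(tree: UnrootedTree, clade: int, matrix: CharacterMatrix) -> UnrootedTree:
    """Cheapest SPR neighbour not displaying ``clade`` (or the tree itself)."""
    if not tree.contains_clade(clade):
        return tree
    best, best_len = None, None
    for cand in tree.spr_neighbours():
        if cand.contains_clade(clade):
            continue
        length, _ = fitch_length(cand, matrix)
        if best_len is None or length < best_len:
            best, best_len = cand, length
    if best is None:
        raise InvalidInputError("could not construct a tree lacking the clade")
    return best


def exhaustive_search(
    matrix: CharacterMatrix, *, archive_window: int = 10**9
) -> SearchResult:
    """Score every unrooted binary topology (feasible to ~9 taxa).

    Populates the archive completely, so decay indices and near-optimal
    consensus trees computed from the result are exact.
    """
    best_len = None
    best = {}
    archive = {}
    for tree in all_topologies(matrix.n_taxa):
        length, _ = fitch_length(tree, matrix)
        if best_len is None or length < best_len:
            best_len = length
            best.clear()
        if length == best_len:
            best.setdefault(tree.topology_key(), tree)
        archive[tree.topology_key()] = (length, tree)
    archive = {k: v for k, v in archive.items() if v[0] <= best_len + archive_window}
    trees = list(best.values())
    return SearchResult(
        best_length=int(best_len),
        best_trees=trees,
        per_char_steps=fitch_steps(trees[0], matrix),
        archive=archive,
        archive_window=archive_window,
    )


# ---------------------------------------------------------------------------
# Support measures
# ---------------------------------------------------------------------------

def bootstrap_support(
    matrix: CharacterMatrix,
    *,
    replicates: int = 100,
    seed: int = 0,
    iterations: int = 5,
    n_starts: int = 1,
) -> dict[int, float]:
    """Bipartition frequencies (%) across bootstrap pseudoreplicates.

    Characters are resampled with replacement per replicate; each replicate
    is analysed with a reduced-effort ratchet and contributes the strict
    consensus bipartitions of its best trees.
    """
    if replicates < 1:
        raise InvalidInputError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}
    for _ in range(replicates):
        rep = matrix.resampled(rng)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        res = ratchet_search(
            rep, iterations=iterations, n_starts=n_starts, seed=rep_seed,
            archive_window=0,
        )
        bips = frozenset.intersection(*(t.bipartitions() for t in res.best_trees))
        for mask in bips:
            counts[mask] = counts.get(mask, 0) + 1
    return {mask: 100.0 * c / replicates for mask, c in counts.items()}


def bremer_decay(
    matrix: CharacterMatrix,
    result: SearchResult,
    clades: list[int] | None = None,
    *,
    seed: int = 0,
    iterations: int = 10,
    n_starts: int = 2,
    use_constraint_search: bool = True,
) -> dict[int, int]:
    """Decay index per clade: extra steps needed to lose it.

    For each clade of the strict consensus of the best trees, the shortest
    tree *not* displaying the clade is sought with a converse-constraint
    ratchet (falling back on the suboptimal-tree archive when disabled);
    B is its length minus the best length.
    """
    cons = strict_consensus(result.best_trees)
    cons_bips = cons.bipartitions()
    if clades is None:
        clades = sorted(cons_bips)
    out = {}
    rng = np.random.default_rng(seed)
    for mask in clades:
        if mask not in cons_bips:
            out[mask] = 0
            continue
        if use_constraint_search:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = ratchet_search(
                matrix, iterations=iterations, n_starts=n_starts, seed=sub_seed,
                archive_window=0, forbidden_clade=mask,
            )
            shortest_without = res.best_length
        else:
            lengths = [
                length
                for (length, t) in result.archive.values()
                if not t.contains_clade(mask)
            ]
            if not lengths:
                raise InvalidInputError(
                    "archive holds no tree lacking the clade; widen the archive "
                    "or enable the constraint search"
                )
            shortest_without = min(lengths)
        out[mask] = int(shortest_without - result.best_length)
    return out


def near_optimal_consensus(result: SearchResult, extra_steps: int) -> UnrootedTree:
    """Strict consensus of all archived trees within ``extra_steps`` of best."""
    if extra_steps > result.archive_window:
        raise InvalidInputError(
            f"archive only covers {result.archive_window} extra steps; "
            f"re-run the search with a wider archive_window"
        )
    trees = result.trees_within(extra_steps)
    if not trees:
        raise InvalidInputError("archive is empty at this suboptimality window")
    return strict_consensus(trees)
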