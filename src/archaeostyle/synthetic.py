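"""Seeded generators for every input the two analysis stages read.

Covers (i) discrete morphological matrices evolved under a k-state
symmetric Markov (Mk) model on a simulated birth (Yule) tree, with missing
and polymorphic cells injected at set rates, and (ii) parametric bilateral
jaw fixtures — tapered-prism hemimandible meshes with graded tooth-radius
landmark rows — plus noisy roll-vs-gape observation tables for axis
calibration.  Every generator is reproducible from an integer seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .jaw import (
    HingeAxisSpec,
    JawAssembly,
    RollCurve,
    build_assembly,
    roll_curve,
)
from .parsimony import CharacterMatrix
from .registration import LandmarkSet, TriangleMesh
from .trees import UnrootedTree


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class SimNode:
    """Node of a rooted simulated tree; ``length`` is the parent-edge length
    in expected substitutions per character."""

    taxon: int | None = None
    length: float = 0.0
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SimNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self, names=None) -> str:
        def render(n):
            if n.is_leaf():
                label = names[n.taxon] if names else f"T{n.taxon}"
                return f"{label}:{n.length:.6f}"
            inner = ",".join(render(c) for c in n.children)
            return f"({inner}):{n.length:.6f}"

        return render(self)[: -len(f":{self.length:.6f}")] + ";"

    def topology(self, n_taxa: int) -> UnrootedTree:
        """Unrooted topology over taxon indices, for tree-distance checks."""
        tree = UnrootedTree.__new__(UnrootedTree)
        tree.n_taxa = n_taxa
        adj: dict[int, set[int]] = {}
        next_id = [n_taxa]

        def walk(node) -> int:
            if node.is_leaf():
                return node.taxon
            nid = next_id[0]
            next_id[0] += 1
            adj.setdefault(nid, set())
            for c in node.children:
                cid = walk(c)
                adj[nid].add(cid)
                adj.setdefault(cid, set()).add(nid)
            return nid

        root_id = walk(self)
        # suppress the degree-2 root of the rooted representation
        if len(adj[root_id]) == 2:
            a, b = adj.pop(root_id)
            adj[a].discard(root_id)
            adj[b].discard(root_id)
            adj[a].add(b)
            adj[b].add(a)
        tree.adj = adj
        tree._next_id = next_id[0]
        return tree


def simulate_tree(
    n_taxa: int,
    seed: int,
    *,
    birth_rate: float = 1.0,
    total_depth: float | None = None,
    branch_length: float | None = None,
) -> SimNode:
    """Yule (pure-birth) tree with exponential waiting times.

    ``total_depth`` rescales the tree so the root-to-tip expected number of
    substitutions is fixed — the knob controlling homoplasy in downstream
    Mk simulation.  ``branch_length`` instead sets *every* branch to a
    constant expected number of substitutions: under pure Yule scaling,
    interior branches can be arbitrarily short and carry no character
    signal, so topology-recovery experiments use a constant per-branch
    length (signal on every split) rather than clock-scaled lengths.
    """
    if n_taxa < 3:
        raise InvalidInputError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    root = SimNode()
    root.children = [SimNode(), SimNode()]
    tips = list(root.children)
    while len(tips) < n_taxa:
        dt = rng.exponential(1.0 / (birth_rate * len(tips)))
        for tip in tips:
            tip.length += dt
        idx = int(rng.integers(0, len(tips)))
        parent = tips.pop(idx)
        parent.children = [SimNode(), SimNode()]
        tips.extend(parent.children)
    dt = rng.exponential(1.0 / (birth_rate * len(tips)))
    for tip in tips:
        tip.length += dt
    order = rng.permutation(n_taxa)
    for i, tip in enumerate(tips):
        tip.taxon = int(order[i])
    if branch_length is not None:
        _set_lengths(root, branch_length)
    elif total_depth is not None:
        depth = _max_depth(root)
        scale = total_depth / depth if depth > 0 else 1.0
        _scale_lengths(root, scale)
    return root


def _set_lengths(node: SimNode, x: float) -> None:
    node.length = x
    for c in node.children:
        _set_lengths(c, x)


def _max_depth(node: SimNode) -> float:
    if node.is_leaf():
        return node.length
    return node.length + max(_max_depth(c) for c in node.children)


def _scale_lengths(node: SimNode, s: float) -> None:
    node.length *= s
    for c in node.children:
        _scale_lengths(c, s)


# ---------------------------------------------------------------------------
# Mk character simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MkSimulationSpec:
    """Study conditions for matrix simulation.

    Defaults mirror a desk-scale version of a morphological dataset: the
    full-size condition (64 taxa, 230 characters) is available by passing
    those numbers, tests default to 12 x 100 for speed.
    """

    tree: SimNode = None  # type: ignore[assignment]
    n_characters: int = 100
    n_states: int = 2
    missing_fraction: float = 0.0
    polymorphism_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.tree is None:
            raise InvalidInputError("a simulated tree is required")
        if not 2 <= self.n_states <= 10:
            raise InvalidInputError("n_states must be in 2..10")
        for frac in (self.missing_fraction, self.polymorphism_fraction):
            if not 0.0 <= frac < 1.0:
                raise InvalidInputError("fractions must be in [0, 1)")


def simulate_matrix(spec: MkSimulationSpec) -> CharacterMatrix:
    """Evolve characters independently under the k-state symmetric model.

    Transition probability along a branch of length t (expected
    substitutions): stay = 1/k + (k-1)/k * exp(-k t / (k-1)); each
    alternative state is reached with equal probability.  Missing cells are
    then masked to the full state set and polymorphic cells widened by one
    extra observed state, at the requested rates.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_states
    nc = spec.n_characters
    leaves = spec.tree.leaves()
    n_taxa = len(leaves)
    states: dict[int, np.ndarray] = {}

    def evolve(parent_states: np.ndarray, t: float) -> np.ndarray:
        p_stay = 1.0 / k + (k - 1.0) / k * np.exp(-k * t / (k - 1.0))
        change = rng.random(nc) >= p_stay
        jump = rng.integers(1, k, size=nc)
        return np.where(change, (parent_states + jump) % k, parent_states)

    def walk(node, state):
        if node.is_leaf():
            states[node.taxon] = state
            return
        for child in node.children:
            walk(child, evolve(state, child.length))

    walk(spec.tree, rng.integers(0, k, size=nc))
    masks = np.zeros((n_taxa, nc), dtype=np.int64)
    for i in range(n_taxa):
        masks[i] = 1 << states[i].astype(np.int64)
    symbols = "0123456789"[:k]
    full = (1 << k) - 1
    if spec.polymorphism_fraction > 0:
        poly = rng.random((n_taxa, nc)) < spec.polymorphism_fraction
        extra = 1 << ((states_arr(states, n_taxa, nc) + rng.integers(1, k, (n_taxa, nc))) % k)
        masks = np.where(poly, masks | extra.astype(np.int64), masks)
    if spec.missing_fraction > 0:
        miss = rng.random((n_taxa, nc)) < spec.missing_fraction
        masks = np.where(miss, full, masks)
    taxa = tuple(f"T{i}" for i in range(n_taxa))
    return CharacterMatrix(taxa=taxa, masks=masks, symbols=symbols)


def states_arr(states: dict[int, np.ndarray], n_taxa: int, nc: int) -> np.ndarray:
    out = np.empty((n_taxa, nc), dtype=np.int64)
    for i in range(n_taxa):
        out[i] = states[i]
    return out


# ---------------------------------------------------------------------------
# Jaw fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JawFixtureSpec:
    """Parametric bilateral jaw stand-in for the scanned cartilages."""

    jaw_length: float = 30.0
    closed_symphysial_angle: float = 50.0
    axis_spec: HingeAxisSpec = field(default_factory=HingeAxisSpec)
    tooth_count: int = 9
    tooth_radius_min: float = 3.0
    tooth_radius_max: float = 6.0
    depth: float = 4.0

    def __post_init__(self):
        if self.jaw_length <= 0 or self.depth <= 0:
            raise InvalidInputError("dimensions must be positive")
        if self.tooth_count < 1:
            raise InvalidInputError("need at least one tooth family")
        if not self.tooth_radius_min < self.tooth_radius_max:
            raise InvalidInputError("tooth radii must grade upward labially")


def synthetic_jaw_fixture(
    spec: JawFixtureSpec = JawFixtureSpec(),
) -> tuple[JawAssembly, TriangleMesh, LandmarkSet]:
    """Mirror-symmetric assembly plus a watertight tapered-prism mesh.

    The mesh is one hemimandible in its local frame: a rectangular prism
    tapering anteriorly (the slender symphysial tip), long axis +x, teeth
    represented as named landmarks at graded radii (lingual small, labial
    large) rather than mesh geometry.
    """
    radii = np.linspace(spec.tooth_radius_min, spec.tooth_radius_max, spec.tooth_count)
    axial = np.linspace(0.3, 0.9, spec.tooth_count) * spec.jaw_length
    assembly = build_assembly(
        spec.axis_spec,
        jaw_length=spec.jaw_length,
        closed_symphysial_angle=spec.closed_symphysial_angle,
        tooth_radii=radii,
        tooth_axial_positions=axial,
    )
    L, d = spec.jaw_length, spec.depth
    # tapered prism: full cross-section at the hinge end, pointed tip ring
    verts = np.array(
        [
            [0, -d / 2, -d / 2], [0, d / 2, -d / 2],
            [0, d / 2, d / 2], [0, -d / 2, d / 2],
            [L, -d / 8, -d / 8], [L, d / 8, -d / 8],
            [L, d / 8, d / 8], [L, -d / 8, d / 8],
        ],
        dtype=float,
    )
    quads = [
        (0, 1, 2, 3)[::-1],  # posterior cap faces -x
        (4, 5, 6, 7),        # anterior cap faces +x
        (0, 4, 5, 1), (1, 5, 6, 2), (2, 6, 7, 3), (3, 7, 4, 0),
    ]
    faces = []
    for a, b, c, dd in quads:
        faces.append((a, b, c))
        faces.append((a, c, dd))
    mesh = TriangleMesh(verts, np.array(faces))
    row = assembly.left.tooth_row
    names = [f"tooth_{i+1}" for i in range(len(row))]
    pts = row.local_positions()
    names += ["hinge", "tip"]
    pts = np.vstack([pts, [0.0, 0.0, 0.0], [L, 0.0, 0.0]])
    landmarks = LandmarkSet(tuple(names), pts)
    return assembly, mesh, landmarks


def synthetic_roll_curve(
    axis_spec: HingeAxisSpec,
    gapes,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RollCurve:
    """Forward-model roll curve with optional seeded Gaussian noise (deg)."""
    assembly = build_assembly(axis_spec)
    curve = roll_curve(assembly, gapes)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        noisy = curve.roll + rng.normal(0.0, noise_sd, size=len(curve.roll))
        if len(curve.gape) and curve.gape[0] == 0.0:
            noisy[0] = 0.0
        return RollCurve(curve.gape, noisy)
    return curve
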