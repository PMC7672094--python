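"""Discrete morphological character matrices and Fitch parsimony.

Characters are unordered and equally weighted unless a weight vector says
otherwise; each matrix cell is a non-empty *state set* over the declared
symbol space, stored as a bitmask (singleton = observed state, full set =
missing ``?`` or gap ``-``, multi-bit = polymorphism).  Step counting is
Fitch's intersection/union pass, vectorised across characters with integer
bit operations.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import (
    InvalidInputError,
    NexusParseError,
    UndefinedIndexError,
)
from .trees import UnrootedTree

_MAXSYMBOLS = 10


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters state-set matrix.

    ``masks[i, j]`` is the bitmask of permitted states of character ``j``
    in taxon ``i`` over ``symbols``; ``orig_indices`` keeps the 1-based
    character numbering of the source matrix across subsetting.
    """

    taxa: tuple[str, ...]
    masks: np.ndarray
    symbols: str = "0123456789"
    orig_indices: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        masks = np.asarray(self.masks, dtype=np.int64)
        if masks.ndim != 2:
            raise InvalidInputError("masks must be 2-D (taxa x characters)")
        if len(self.taxa) != masks.shape[0]:
            raise InvalidInputError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise InvalidInputError("duplicate taxon names")
        if np.any(masks <= 0):
            raise InvalidInputError("every cell must be a non-empty state set")
        full = (1 << len(self.symbols)) - 1
        if np.any(masks & ~full):
            raise InvalidInputError("cell state outside the declared symbol space")
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "masks", masks)
        oi = self.orig_indices
        oi = np.arange(1, masks.shape[1] + 1) if oi is None else np.asarray(oi)
        object.__setattr__(self, "orig_indices", oi)
        w = self.weights
        w = np.ones(masks.shape[1], dtype=int) if w is None else np.asarray(w, int)
        if np.any(w <= 0):
            raise InvalidInputError("weights must be positive integers")
        object.__setattr__(self, "weights", w)

    @property
    def n_taxa(self) -> int:
        return self.masks.shape[0]

    @property
    def n_characters(self) -> int:
        return self.masks.shape[1]

    def full_mask(self) -> int:
        return (1 << len(self.symbols)) - 1

    def reweighted(self, weights: np.ndarray) -> "CharacterMatrix":
        return replace(self, weights=np.asarray(weights, int))

    def resampled(self, rng: np.random.Generator) -> "CharacterMatrix":
        """Bootstrap pseudoreplicate: characters resampled with replacement."""
        idx = rng.integers(0, self.n_characters, size=self.n_characters)
        return replace(
            self,
            masks=self.masks[:, idx],
            orig_indices=self.orig_indices[idx],
            weights=self.weights[idx],
        )


def subset_characters(
    matrix: CharacterMatrix,
    include_ranges: list[tuple[int, int]] | None = None,
    exclude_ranges: list[tuple[int, int]] | None = None,
) -> CharacterMatrix:
    """Character-partition selection by 1-based inclusive original indices.

    Used for partition-exclusion experiments (e.g. restricting the matrix
    to neurocranial, scale, tooth or fin-spine characters).
    """
    if include_ranges and exclude_ranges:
        raise InvalidInputError("give include_ranges or exclude_ranges, not both")
    orig = matrix.orig_indices

    def span_mask(ranges):
        sel = np.zeros(matrix.n_characters, dtype=bool)
        for lo, hi in ranges:
            if lo < 1 or hi < lo:
                raise InvalidInputError(f"bad 1-based range ({lo}, {hi})")
            if hi > orig.max():
                raise InvalidInputError(
                    f"range ({lo}, {hi}) exceeds highest character index {orig.max()}"
                )
            sel |= (orig >= lo) & (orig <= hi)
        return sel

    if include_ranges is not None:
        keep = span_mask(include_ranges)
    elif exclude_ranges is not None:
        keep = ~span_mask(exclude_ranges)
    else:
        raise InvalidInputError("no ranges given")
    return replace(
        matrix,
        masks=matrix.masks[:, keep],
        orig_indices=orig[keep],
        weights=matrix.weights[keep],
    )


def parse_ranges(text: str) -> list[tuple[int, int]]:
    """Parse '1-4,100-180' style range lists (1-based inclusive)."""
    out = []
    for token in text.split(","):
        token = token.strip()
        if "-" in token:
            lo, hi = token.split("-")
            out.append((int(lo), int(hi)))
        else:
            out.append((int(token), int(token)))
    return out


# ---------------------------------------------------------------------------
# NEXUS input
# ---------------------------------------------------------------------------

def read_nexus(path) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    MISSING, GAP and SYMBOLS directives are honoured; ``{}``/``()``
    polymorphisms become multi-state sets; both ``?`` and ``-`` are treated
    as fully missing (any state), the usual convention for morphology.
    """
    import dendropy

    try:
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:
        raise NexusParseError(f"NEXUS parse failed: {exc}") from exc
    taxa = tuple(t.label for t in dmat.taxon_namespace)
    if len(set(taxa)) != len(taxa):
        raise NexusParseError("duplicate taxon names in NEXUS file")
    symbols = "".join(
        s.symbol
        for s in dmat.default_state_alphabet.fundamental_state_iter()
        if s.symbol not in ("-",)
    )
    sym_index = {s: i for i, s in enumerate(symbols)}
    full = (1 << len(symbols)) - 1
    n_char = max(len(dmat[t]) for t in dmat)
    masks = np.zeros((len(taxa), n_char), dtype=np.int64)
    for i, tax in enumerate(dmat.taxon_namespace):
        row = dmat[tax]
        if len(row) != n_char:
            raise NexusParseError(
                f"taxon {tax.label!r} has {len(row)} characters, expected {n_char}"
            )
        for j, st in enumerate(row):
            fund = [s.symbol for s in st.fundamental_states]
            if st.symbol in ("?", "-") or "-" in fund:
                masks[i, j] = full
                continue
            m = 0
            for s in fund:
                if s not in sym_index:
                    raise NexusParseError(
                        f"unknown state symbol {s!r} at taxon {tax.label!r}, "
                        f"character {j + 1}"
                    )
                m |= 1 << sym_index[s]
            masks[i, j] = m
    return CharacterMatrix(taxa=taxa, masks=masks, symbols=symbols)


def write_nexus(matrix: CharacterMatrix, path) -> None:
    sym = matrix.symbols
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="{sym}";',
        "MATRIX",
    ]
    full = matrix.full_mask()
    width = max(len(t) for t in matrix.taxa) + 2
    for i, name in enumerate(matrix.taxa):
        cells = []
        for m in matrix.masks[i]:
            if m == full:
                cells.append("?")
            else:
                states = [sym[k] for k in range(len(sym)) if m >> k & 1]
                cells.append(states[0] if len(states) == 1 else "{" + "".join(states) + "}")
        safe = name.replace(" ", "_")
        lines.append(f"{safe:<{width}}" + "".join(cells))
    lines += [";", "END;", ""]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Fitch step counting
# ---------------------------------------------------------------------------

def fitch_steps(tree: UnrootedTree, matrix: CharacterMatrix) -> np.ndarray:
    """Unweighted Fitch step count per character on a binary tree."""
    if tree.n_taxa != matrix.n_taxa:
        raise InvalidInputError(
            f"tree has {tree.n_taxa} leaves but matrix has {matrix.n_taxa} taxa"
        )
    masks = matrix.masks
    steps = np.zeros(matrix.n_characters, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for node, parent in tree.postorder(0):
        if node < tree.n_taxa:
            sets[node] = masks[node]
            continue
        acc = None
        for child in tree.adj[node]:
            if child == parent:
                continue
            cs = sets[child]
            if acc is None:
                acc = cs
                continue
            inter = acc & cs
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | cs, inter)
        sets[node] = acc
    # close the root edge against taxon 0
    root = next(iter(tree.adj[0]))
    steps += (sets[root] & masks[0]) == 0
    return steps


def fitch_length(tree: UnrootedTree, matrix: CharacterMatrix) -> tuple[int, np.ndarray]:
    """Weighted tree length and per-character steps."""
    s = fitch_steps(tree, matrix)
    return int((s * matrix.weights).sum()), s


# ---------------------------------------------------------------------------
# Homoplasy bounds and ensemble indices
# ---------------------------------------------------------------------------

def char_step_bounds(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-character minimum (m) and maximum (g) possible steps on any tree.

    Both tallies use only unambiguous singleton codings: ``m`` is one less
    than the number of distinct observed states (floor 0); ``g`` is the
    steps on the worst tree, the number of coded taxa minus the count of
    the most frequent state.
    """
    masks = matrix.masks
    singleton = (masks & (masks - 1)) == 0
    n_char = matrix.n_characters
    m = np.zeros(n_char, dtype=np.int64)
    g = np.zeros(n_char, dtype=np.int64)
    for j in range(n_char):
        col = masks[singleton[:, j], j]
        if len(col) == 0:
            continue
        _, counts = np.unique(col, return_counts=True)
        m[j] = max(len(counts) - 1, 0)
        g[j] = len(col) - counts.max()
    return m, g


@dataclass(frozen=True)
class FitIndices:
    """Ensemble consistency (CI), retention (RI) and rescaled (RC) indices."""

    min_steps: np.ndarray
    observed_steps: np.ndarray
    max_steps: np.ndarray
    ci: float
    ri: float
    rc: float
    ci_informative: float
    ri_informative: float
    rc_informative: float


def ensemble_indices(
    observed_steps: np.ndarray, matrix: CharacterMatrix
) -> FitIndices:
    """CI = Σm/Σs, RI = (Σg−Σs)/(Σg−Σm), RC = CI·RI on a representative tree.

    Reported twice: over all characters and over parsimony-informative
    characters only (a character is uninformative when its best and worst
    cases coincide, m = g).
    """
    s = np.asarray(observed_steps, dtype=np.int64)
    m, g = char_step_bounds(matrix)
    w = matrix.weights

    def indices(sel):
        sw = float((s[sel] * w[sel]).sum())
        mw = float((m[sel] * w[sel]).sum())
        gw = float((g[sel] * w[sel]).sum())
        if sw == 0:
            raise UndefinedIndexError(
                "no observed steps on any selected character; CI undefined"
            )
        ci = mw / sw
        ri = (gw - sw) / (gw - mw) if gw > mw else 1.0 if gw == sw else 0.0
        return ci, ri, ci * ri

    all_sel = np.ones(len(s), dtype=bool)
    ci, ri, rc = indices(all_sel)
    informative = g > m
    if informative.any():
        ci_i, ri_i, rc_i = indices(informative)
    else:
        ci_i = ri_i = rc_i = float("nan")
    return FitIndices(
        min_steps=m, observed_steps=s, max_steps=g,
        ci=ci, ri=ri, rc=rc,
        ci_informative=ci_i, ri_informative=ri_i, rc_informative=rc_i,
    )
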