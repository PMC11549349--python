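"""Parsimony tree length: Fitch (unordered) and Farris (ordered) passes.

Characters are evaluated vectorized across columns.  Unordered characters
use bitmask state sets (missing and inapplicable cells are fully
ambiguous; polymorphic cells contribute their state set); ordered
characters use the bounded-interval pass, with polymorphic cells reduced
to their [min, max] interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from paleosnake.errors import ValidationError
from paleosnake.parsimony.matrix import CharacterMatrix, Ordering
from paleosnake.parsimony.tree import PhyloTree, postorder_nodes


@dataclass
class EncodedMatrix:
    """Numeric encoding of a CharacterMatrix for fast length evaluation."""

    taxa: tuple[str, ...]
    # unordered characters
    u_masks: np.ndarray   # (n_taxa, m_u) uint64 bitmasks
    u_weights: np.ndarray  # (m_u,) int
    # ordered characters
    o_lo: np.ndarray      # (n_taxa, m_o) int
    o_hi: np.ndarray      # (n_taxa, m_o) int
    o_weights: np.ndarray  # (m_o,) int

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


def encode_matrix(matrix: CharacterMatrix) -> EncodedMatrix:
    """Encode the active characters of a matrix (cached on the matrix)."""
    cached = getattr(matrix, "_encoded", None)
    if cached is not None:
        return cached
    n = matrix.n_taxa
    u_cols, u_w, o_cols_lo, o_cols_hi, o_w = [], [], [], [], []
    for j in range(matrix.n_char):
        if not matrix.active[j]:
            continue
        observed = matrix.observed_states(j)
        if matrix.ordering[j] is Ordering.ORDERED:
            lo_default = min(observed) if observed else 0
            hi_default = max(observed) if observed else 0
            lo = np.empty(n, dtype=np.int64)
            hi = np.empty(n, dtype=np.int64)
            for i in range(n):
                cell = matrix.cells[i][j]
                if isinstance(cell, frozenset) and cell:
                    lo[i], hi[i] = min(cell), max(cell)
                else:
                    lo[i], hi[i] = lo_default, hi_default
            o_cols_lo.append(lo)
            o_cols_hi.append(hi)
            o_w.append(matrix.weights[j])
        else:
            top = max(observed) if observed else 0
            if top > 62:
                raise ValidationError(
                    f"character {j}: states above 62 unsupported in bitmask encoding"
                )
            full = (1 << (top + 1)) - 1
            col = np.empty(n, dtype=np.uint64)
            for i in range(n):
                cell = matrix.cells[i][j]
                if isinstance(cell, frozenset) and cell:
                    m = 0
                    for s in cell:
                        m |= 1 << s
                    col[i] = m
                else:
                    col[i] = full
            u_cols.append(col)
            u_w.append(matrix.weights[j])
    enc = EncodedMatrix(
        taxa=tuple(matrix.taxa),
        u_masks=(
            np.stack(u_cols, axis=1)
            if u_cols
            else np.zeros((n, 0), dtype=np.uint64)
        ),
        u_weights=np.asarray(u_w, dtype=np.int64),
        o_lo=(
            np.stack(o_cols_lo, axis=1)
            if o_cols_lo
            else np.zeros((n, 0), dtype=np.int64)
        ),
        o_hi=(
            np.stack(o_cols_hi, axis=1)
            if o_cols_hi
            else np.zeros((n, 0), dtype=np.int64)
        ),
        o_weights=np.asarray(o_w, dtype=np.int64),
    )
    matrix._encoded = enc
    return enc


def _length_encoded(
    enc: EncodedMatrix,
    order: list[tuple[int, tuple[int, ...]]],
    anchor: int = 0,
) -> int:
    """Length given a postorder rooted at leaf ``anchor``'s neighbor."""
    total = 0
    have_u = enc.u_masks.shape[1] > 0
    have_o = enc.o_lo.shape[1] > 0
    other = 1 if anchor == 0 else 0  # partner leaf in the 2-leaf degenerate case

    if have_u:
        states: dict[int, np.ndarray] = {}
        w = enc.u_weights
        masks = enc.u_masks
        n = enc.n_taxa
        for node, children in order:
            acc = states[children[0]] if children[0] >= n else masks[children[0]]
            for c in children[1:]:
                st = states[c] if c >= n else masks[c]
                inter = acc & st
                conflict = inter == 0
                total += int(w[conflict].sum())
                acc = np.where(conflict, acc | st, inter)
            states[node] = acc
        root_state = states[order[-1][0]] if order else masks[other]
        conflict = (root_state & masks[anchor]) == 0
        total += int(w[conflict].sum())

    if have_o:
        lows: dict[int, np.ndarray] = {}
        highs: dict[int, np.ndarray] = {}
        w = enc.o_weights
        lo_leaf, hi_leaf = enc.o_lo, enc.o_hi
        n = enc.n_taxa
        for node, children in order:
            c0 = children[0]
            lo = lows[c0] if c0 >= n else lo_leaf[c0]
            hi = highs[c0] if c0 >= n else hi_leaf[c0]
            for c in children[1:]:
                lo2 = lows[c] if c >= n else lo_leaf[c]
                hi2 = highs[c] if c >= n else hi_leaf[c]
                a = np.maximum(lo, lo2)
                b = np.minimum(hi, hi2)
                gap = np.maximum(a - b, 0)
                total += int((w * gap).sum())
                lo, hi = np.minimum(a, b), np.maximum(a, b)
            lows[node], highs[node] = lo, hi
        root = order[-1][0] if order else other
        lo = lows[root] if root >= n else lo_leaf[root]
        hi = highs[root] if root >= n else hi_leaf[root]
        a = np.maximum(lo, lo_leaf[anchor])
        b = np.minimum(hi, hi_leaf[anchor])
        total += int((w * np.maximum(a - b, 0)).sum())

    return total


def tree_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Weighted minimum number of state changes of the matrix on the tree."""
    if tuple(tree.taxa) != tuple(matrix.taxa):
        raise ValidationError("tree taxa do not match matrix taxa")
    enc = encode_matrix(matrix)
    return _length_encoded(enc, postorder_nodes(tree))


# ---------------------------------------------------------------------------
# per-character bounds for the ensemble indices


def min_steps(matrix: CharacterMatrix, j: int) -> int:
    """Minimum conceivable steps of character j on any tree."""
    observed = matrix.observed_states(j)
    if len(observed) <= 1:
        return 0
    cells = [
        c for c in (matrix.cells[i][j] for i in range(matrix.n_taxa))
        if isinstance(c, frozenset) and c
    ]
    if matrix.ordering[j] is Ordering.ORDERED:
        # leaves choose freely within their intervals; minimal spread
        return max(0, max(min(c) for c in cells) - min(max(c) for c in cells))
    # greedy set cover: monomorphic states are forced; a polymorphic cell
    # only forces a new state when it shares none with the forced set
    forced = {next(iter(c)) for c in cells if len(c) == 1}
    for c in sorted((c for c in cells if len(c) > 1), key=sorted):
        if not (c & forced):
            forced.add(min(c))
    return max(0, len(forced) - 1)


def max_steps(matrix: CharacterMatrix, j: int) -> int:
    """Maximum steps of character j over all trees (its star-tree length)."""
    cells = [
        c for c in (matrix.cells[i][j] for i in range(matrix.n_taxa))
        if isinstance(c, frozenset) and c
    ]
    if len(cells) <= 1:
        return 0
    if matrix.ordering[j] is Ordering.ORDERED:
        lo = min(min(c) for c in cells)
        hi = max(max(c) for c in cells)
        best = None
        for center in range(lo, hi + 1):
            cost = sum(
                max(min(c) - center, center - max(c), 0) for c in cells
            )
            best = cost if best is None else min(best, cost)
        return int(best or 0)
    states = set().union(*cells)
    best_match = max(sum(1 for c in cells if s in c) for s in states)
    return len(cells) - best_match
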