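"""Independent oracles used by the test suite.

These stay deliberately naive and separate from the implementation they
check: exhaustive enumeration of unrooted topologies, and a uniform-cost
Sankoff dynamic program for tree length.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from paleosnake.parsimony.matrix import CharacterMatrix, Ordering
from paleosnake.parsimony.tree import PhyloTree, postorder_nodes

INF = 10**9


def all_topologies(taxa: tuple[str, ...]) -> list[PhyloTree]:
    """Every unrooted binary topology on the taxon list (by leaf insertion)."""
    n = len(taxa)
    adjs = [{0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}]
    for leaf in range(3, n):
        grown = []
        for adj in adjs:
            edges = [(u, v) for u in adj for v in adj[u] if u < v]
            for u, v in edges:
                a = {k: set(vs) for k, vs in adj.items()}
                w = max(a) + 1
                a[u].discard(v)
                a[v].discard(u)
                a[w] = {u, v, leaf}
                a[u].add(w)
                a[v].add(w)
                a[leaf] = {w}
                grown.append(a)
        adjs = grown
    return [PhyloTree(taxa, a) for a in adjs]


def sankoff_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Tree length by per-character Sankoff DP (uniform cost for unordered
    characters, |i-j| cost for ordered); missing/inapplicable cells cost 0
    in every state."""
    order = postorder_nodes(tree)
    total = 0
    for j in range(matrix.n_char):
        if not matrix.active[j]:
            continue
        observed = matrix.observed_states(j)
        if not observed:
            continue
        k = max(observed) + 1
        ordered = matrix.ordering[j] is Ordering.ORDERED

        def cost(a: int, b: int) -> int:
            return abs(a - b) if ordered else int(a != b)

        def leaf_vec(i: int) -> list[int]:
            cell = matrix.cells[i][j]
            if isinstance(cell, frozenset):
                return [0 if s in cell else INF for s in range(k)]
            return [0] * k

        vec: dict[int, list[int]] = {}
        for node, children in order:
            acc = [0] * k
            for c in children:
                child = vec[c] if c >= matrix.n_taxa else leaf_vec(c)
                for s in range(k):
                    acc[s] += min(child[t] + cost(s, t) for t in range(k))
            vec[node] = acc
        root = order[-1][0] if order else None
        anchor = leaf_vec(0)
        if root is None:
            other = leaf_vec(1)
            best = min(anchor[s] + min(other[t] + cost(s, t) for t in range(k))
                       for s in range(k))
        else:
            best = min(
                anchor[s] + min(vec[root][t] + cost(s, t) for t in range(k))
                for s in range(k)
            )
        total += matrix.weights[j] * best
    return total


def random_binary_matrix(
    taxa: list[str], n_char: int, rng: np.random.Generator,
    missing_frac: float = 0.0,
) -> CharacterMatrix:
    cells = []
    for _ in taxa:
        row = []
        for _ in range(n_char):
            if missing_frac and rng.random() < missing_frac:
                from paleosnake.parsimony.matrix import MISSING

                row.append(MISSING)
            else:
                row.append(frozenset({int(rng.integers(0, 2))}))
        cells.append(row)
    return CharacterMatrix(taxa=list(taxa), cells=cells)
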