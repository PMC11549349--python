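"""Heuristic maximum-parsimony search: Wagner trees improved by TBR.

The protocol mirrors a classic "traditional search": a number of
random-addition-sequence replicates each build a greedy Wagner starting
tree, then improve it by tree-bisection-reconnection (TBR) branch
swapping, retaining up to a fixed number of equally short trees per
replicate.  The global pool is deduplicated by bipartition set, capped,
and filtered to the overall minimum length.  Everything is driven by one
seeded generator, so a run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from paleosnake.errors import ValidationError
from paleosnake.parsimony.length import (
    EncodedMatrix,
    _length_encoded,
    encode_matrix,
    max_steps,
    min_steps,
)
from paleosnake.parsimony.matrix import CharacterMatrix
from paleosnake.parsimony.tree import PhyloTree

Adj = dict[int, set[int]]


# -- adjacency plumbing ------------------------------------------------------


def _copy(adj: Adj) -> Adj:
    return {u: set(vs) for u, vs in adj.items()}


def _edges(adj: Adj) -> list[tuple[int, int]]:
    return [(u, v) for u in sorted(adj) for v in sorted(adj[u]) if u < v]


def _postorder(
    adj: Adj, n_leaves: int, anchor: int
) -> list[tuple[int, tuple[int, ...]]]:
    """Postorder rooted at ``anchor``'s neighbor (anchor = lowest leaf present,
    so partially built Wagner trees are handled too)."""
    if len(adj) < 3:
        return []
    root = next(iter(adj[anchor]))
    out: list[tuple[int, tuple[int, ...]]] = []
    stack: list[tuple[int, int, bool]] = [(root, anchor, False)]
    while stack:
        node, parent, expanded = stack.pop()
        children = tuple(nb for nb in adj[node] if nb != parent)
        if expanded:
            out.append((node, children))
        else:
            stack.append((node, parent, True))
            for c in children:
                if c >= n_leaves:
                    stack.append((c, node, False))
    return out


def _length(adj: Adj, enc: EncodedMatrix) -> int:
    anchor = min(u for u in adj if u < enc.n_taxa)
    return _length_encoded(enc, _postorder(adj, enc.n_taxa, anchor), anchor)


def _splits_key(adj: Adj, n_leaves: int) -> frozenset[int]:
    full = (1 << n_leaves) - 1
    masks: dict[int, int] = {i: 1 << i for i in range(n_leaves)}
    splits = set()
    for node, children in _postorder(adj, n_leaves, 0):
        m = 0
        for c in children:
            m |= masks[c]
        masks[node] = m
        side = m if not (m & 1) else (full ^ m)
        if 2 <= side.bit_count() <= n_leaves - 2:
            splits.add(side)
    return frozenset(splits)


def _attach_leaf(adj: Adj, leaf: int, edge: tuple[int, int], new_internal: int) -> None:
    u, v = edge
    adj[u].discard(v)
    adj[v].discard(u)
    adj[new_internal] = {u, v, leaf}
    adj[u].add(new_internal)
    adj[v].add(new_internal)
    adj.setdefault(leaf, set()).add(new_internal)


def _detach_leaf(adj: Adj, leaf: int, internal: int) -> None:
    nbs = adj[internal] - {leaf}
    u, v = sorted(nbs)
    del adj[internal]
    adj[leaf].discard(internal)
    adj[u].discard(internal)
    adj[v].discard(internal)
    adj[u].add(v)
    adj[v].add(u)


def to_phylo(adj: Adj, taxa) -> PhyloTree:
    return PhyloTree(taxa, _copy(adj))


# -- Wagner addition ---------------------------------------------------------


def wagner_tree(enc: EncodedMatrix, rng: np.random.Generator) -> Adj:
    """Greedy random-addition-sequence starting tree."""
    n = enc.n_taxa
    if n < 4:
        raise ValidationError("need at least 4 taxa")
    order = list(rng.permutation(n))
    a, b, c = order[:3]
    hub = n  # first internal node id
    adj: Adj = {a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}
    next_id = n + 1
    for leaf in order[3:]:
        best_len: Optional[int] = None
        best_edge: Optional[tuple[int, int]] = None
        for edge in _edges(adj):
            _attach_leaf(adj, leaf, edge, next_id)
            score = _length(adj, enc)
            _detach_leaf(adj, leaf, next_id)
            if best_len is None or score < best_len:
                best_len, best_edge = score, edge
        assert best_edge is not None
        _attach_leaf(adj, leaf, best_edge, next_id)
        next_id += 1
    return adj


# -- TBR ---------------------------------------------------------------------


def _component(adj: Adj, start: int, blocked: frozenset[int]) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen and (u, v) not in blocked and (v, u) not in blocked:
                seen.add(v)
                stack.append(v)
    return seen


def tbr_neighbors(adj: Adj, n_leaves: int) -> Iterator[Adj]:
    """All TBR rearrangements of an unrooted binary tree, in a fixed order.

    Each tree edge is bisected; the two resulting subtrees are rejoined by
    a new edge between the midpoints of every pair of (subtree-edge,
    subtree-edge) attachment points.  Single-leaf components attach at the
    leaf itself.  The original topology is among the yields (at the original
    attachment points); callers dedupe by split set.
    """
    base_edges = _edges(adj)
    max_id = max(adj)
    for cut in base_edges:
        u, v = cut
        work = _copy(adj)
        work[u].discard(v)
        work[v].discard(u)
        comp_u = _component(work, u, frozenset())
        comp_v = _component(work, v, frozenset())

        def prepare(side_root: int, comp: set[int]) -> tuple[Adj, list]:
            """Suppress the degree-2 stump; return component + attach points."""
            sub = {x: set(work[x]) & comp for x in comp}
            stump = side_root
            if stump >= n_leaves and len(sub[stump]) == 2:
                a, b = sorted(sub[stump])
                sub[a].discard(stump)
                sub[b].discard(stump)
                sub[a].add(b)
                sub[b].add(a)
                del sub[stump]
            points: list = [(x, y) for x in sorted(sub) for y in sorted(sub[x]) if x < y]
            if not points:  # single node (a bare leaf, or stump-only)
                points = [next(iter(sub))]
            return sub, points

        sub_u, pts_u = prepare(u, comp_u)
        sub_v, pts_v = prepare(v, comp_v)
        for pu in pts_u:
            for pv in pts_v:
                new: Adj = {}
                for part in (sub_u, sub_v):
                    for x, ys in part.items():
                        new[x] = set(ys)
                nid = max_id + 1

                def endpoint(p, counter):
                    nonlocal new
                    if isinstance(p, tuple):
                        a, b = p
                        new[a].discard(b)
                        new[b].discard(a)
                        new[counter] = {a, b}
                        new[a].add(counter)
                        new[b].add(counter)
                        return counter, counter + 1
                    return p, counter

                eu, nid = endpoint(pu, nid)
                ev, nid = endpoint(pv, nid)
                new[eu].add(ev)
                new[ev].add(eu)
                yield new


# -- search ------------------------------------------------------------------


@dataclass
class SearchResult:
    """Outcome of a heuristic search, with ensemble fit statistics."""

    best_length: int
    trees: list[PhyloTree]
    n_replicates: int
    trees_per_rep: int
    maxtrees: int
    seed: int
    per_character_min: list[int] = field(default_factory=list)
    per_character_max: list[int] = field(default_factory=list)
    ci: Optional[float] = None
    ri: Optional[float] = None
    replicate_lengths: list[int] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "best_length": self.best_length,
            "n_trees": len(self.trees),
            "n_replicates": self.n_replicates,
            "trees_per_rep": self.trees_per_rep,
            "maxtrees": self.maxtrees,
            "seed": self.seed,
            "ci": self.ci,
            "ri": self.ri,
            "replicate_lengths": self.replicate_lengths,
        }


def _swap_to_optimum(
    start: Adj, enc: EncodedMatrix, trees_per_rep: int
) -> tuple[int, list[Adj]]:
    """TBR hill-climb from one starting tree, collecting a plateau.

    Accepts strictly better neighbors immediately (monotone descent); on a
    plateau, collects up to ``trees_per_rep`` distinct equally short trees
    and swaps on each of them once.
    """
    n = enc.n_taxa
    best = _length(start, enc)
    pool: list[Adj] = [start]
    keys = {_splits_key(start, n)}
    queue: list[Adj] = [start]
    while queue:
        current = queue.pop(0)
        restart = False
        for nb in tbr_neighbors(current, n):
            score = _length(nb, enc)
            if score < best:
                best = score
                pool = [nb]
                keys = {_splits_key(nb, n)}
                queue = [nb]
                restart = True
                break
            if score == best and len(pool) < trees_per_rep:
                key = _splits_key(nb, n)
                if key not in keys:
                    keys.add(key)
                    pool.append(nb)
                    queue.append(nb)
        if restart:
            continue
    return best, pool


def heuristic_search(
    matrix: CharacterMatrix,
    n_replicates: int = 50,
    trees_per_rep: int = 10,
    maxtrees: int = 10000,
    seed: int = 0,
) -> SearchResult:
    """Random-addition Wagner + TBR search over a character matrix."""
    if maxtrees < 1:
        raise ValidationError("maxtrees must be >= 1")
    if n_replicates < 1 or trees_per_rep < 1:
        raise ValidationError("n_replicates and trees_per_rep must be >= 1")
    if matrix.n_taxa < 4:
        raise ValidationError("need at least 4 taxa for a search")
    enc = encode_matrix(matrix)
    global_best: Optional[int] = None
    global_pool: list[Adj] = []
    global_keys: set[frozenset[int]] = set()
    replicate_lengths: list[int] = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        start = wagner_tree(enc, rng)
        best, pool = _swap_to_optimum(start, enc, trees_per_rep)
        replicate_lengths.append(best)
        if global_best is None or best < global_best:
            global_best = best
            global_pool = []
            global_keys = set()
        if best == global_best:
            for adj in pool:
                key = _splits_key(adj, enc.n_taxa)
                if key not in global_keys and len(global_pool) < maxtrees:
                    global_keys.add(key)
                    global_pool.append(adj)
    assert global_best is not None
    taxa = tuple(matrix.taxa)
    trees = [to_phylo(adj, taxa) for adj in global_pool]
    result = SearchResult(
        best_length=global_best,
        trees=trees,
        n_replicates=n_replicates,
        trees_per_rep=trees_per_rep,
        maxtrees=maxtrees,
        seed=seed,
        replicate_lengths=replicate_lengths,
    )
    result.per_character_min = [min_steps(matrix, j) for j in range(matrix.n_char)]
    result.per_character_max = [max_steps(matrix, j) for j in range(matrix.n_char)]
    result.ci, result.ri = ensemble_indices(result, matrix)
    return result


def ensemble_indices(
    result: SearchResult,
    matrix: CharacterMatrix,
    informative_only: bool = False,
) -> tuple[float, Optional[float]]:
    """Ensemble consistency and retention indices at the best length.

    CI = sum(w*m) / L where m is each character's minimum conceivable
    steps; RI = (sum(w*G) - L) / (sum(w*G) - sum(w*m)) where G is each
    character's star-tree (maximum) length.  By default all active
    characters contribute, autapomorphies included; ``informative_only``
    drops characters whose minimum equals their maximum.  RI is undefined
    (None) when the matrix carries no retainable variation (sum G == sum m).
    """
    mins = result.per_character_min or [
        min_steps(matrix, j) for j in range(matrix.n_char)
    ]
    maxs = result.per_character_max or [
        max_steps(matrix, j) for j in range(matrix.n_char)
    ]
    sum_m = 0
    sum_g = 0
    for j in range(matrix.n_char):
        if not matrix.active[j]:
            continue
        if informative_only and maxs[j] <= mins[j]:
            continue
        w = matrix.weights[j]
        sum_m += w * mins[j]
        sum_g += w * maxs[j]
    length = result.best_length
    ci = sum_m / length if length > 0 else 1.0
    ri = (sum_g - length) / (sum_g - sum_m) if sum_g > sum_m else None
    return ci, ri
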