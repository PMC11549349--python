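"""Bremer (decay) support from a pool of suboptimal trees.

The decay index of a clade is how many extra steps a tree must accept
before the clade disappears from the near-optimal set.  Following the
suboptimal-pool protocol, the optimal trees are extended by TBR-visiting
every tree within ``margin`` steps of the optimum (up to a pool cap); for
each clade of the reference (majority-rule) tree the decay is the length
excess of the shortest pool tree lacking that clade.  A clade never
contradicted within the margin is reported as ">= margin".  Because the
pool is a sample of tree space, the values are lower-bound estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from paleosnake.errors import ValidationError
from paleosnake.parsimony.length import encode_matrix
from paleosnake.parsimony.matrix import CharacterMatrix
from paleosnake.parsimony.search import (
    SearchResult,
    _copy,
    _length,
    _splits_key,
    tbr_neighbors,
)
from paleosnake.parsimony.tree import PhyloTree, majority_rule


@dataclass
class BremerRow:
    clade: frozenset[str]
    mask: int
    decay: Optional[int]  # None means never contradicted within the margin
    margin: int

    @property
    def display(self) -> str:
        return f">= {self.margin}" if self.decay is None else str(self.decay)


@dataclass
class BremerTable:
    reference: PhyloTree
    rows: list[BremerRow]
    margin: int
    best_length: int
    pool_size: int

    def as_dict(self) -> dict:
        return {
            "margin": self.margin,
            "best_length": self.best_length,
            "pool_size": self.pool_size,
            "clades": [
                {"taxa": sorted(r.clade), "decay": r.display} for r in self.rows
            ],
        }


def bremer_support(
    matrix: CharacterMatrix,
    result: SearchResult,
    margin: int = 20,
    seed: int = 0,
    max_pool: int = 10000,
) -> BremerTable:
    """Decay values for every clade of the majority-rule reference tree."""
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    if not result.trees:
        raise ValidationError("search result holds no trees")
    enc = encode_matrix(matrix)
    n = enc.n_taxa
    best = result.best_length
    limit = best + margin

    reference = majority_rule(result.trees)

    pool: dict[frozenset[int], int] = {}  # splits key -> length
    frontier: list[dict] = []
    for tree in result.trees:
        adj = _copy(tree.adj)
        key = _splits_key(adj, n)
        if key not in pool:
            pool[key] = _length(adj, enc)
            frontier.append(adj)
    while frontier and len(pool) < max_pool:
        adj = frontier.pop(0)
        for nb in tbr_neighbors(adj, n):
            if len(pool) >= max_pool:
                break
            key = _splits_key(nb, n)
            if key in pool:
                continue
            score = _length(nb, enc)
            if score <= limit:
                pool[key] = score
                frontier.append(nb)

    rows = []
    for mask in sorted(reference.bipartitions()):
        lacking = [L for key, L in pool.items() if mask not in key]
        decay = (min(lacking) - best) if lacking else None
        clade = frozenset(
            reference.taxa[i] for i in range(len(reference.taxa)) if mask >> i & 1
        )
        rows.append(BremerRow(clade=clade, mask=mask, decay=decay, margin=margin))
    return BremerTable(
        reference=reference,
        rows=rows,
        margin=margin,
        best_length=best,
        pool_size=len(pool),
    )
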