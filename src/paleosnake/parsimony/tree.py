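"""Unrooted phylogenetic trees, Newick I/O, and consensus methods.

Trees are stored as an adjacency map over integer node ids; leaf ids
``0..n-1`` index into a fixed, ordered taxon tuple.  A topology is
identified by its set of non-trivial bipartitions, each encoded as the
bitmask of the side *not* containing taxon 0 — two trees over the same
taxa are equal iff their bipartition sets are equal.  Search trees are
strictly binary (internal degree 3); consensus trees may be polytomous.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import dendropy

from paleosnake.errors import ParseError, ValidationError


class PhyloTree:
    """An unrooted tree over a fixed taxon set."""

    __slots__ = ("taxa", "adj", "clade_support", "edge_lengths", "_key")

    def __init__(
        self,
        taxa: Sequence[str],
        adj: dict[int, set[int]],
        clade_support: Optional[dict[int, float]] = None,
        edge_lengths: Optional[dict[frozenset[int], float]] = None,
    ):
        self.taxa = tuple(taxa)
        self.adj = adj
        #: optional clade-frequency annotations (bipartition mask -> percent)
        self.clade_support = clade_support
        #: optional branch lengths, keyed by frozenset({u, v})
        self.edge_lengths = edge_lengths
        self._key: Optional[frozenset[int]] = None
        self._validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def is_leaf(self, node: int) -> bool:
        return node < self.n_leaves

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u in sorted(self.adj):
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def _validate(self) -> None:
        n = self.n_leaves
        if len(self.taxa) != len(set(self.taxa)):
            raise ValidationError("duplicate taxon names")
        leaves_seen = [u for u in self.adj if u < n]
        if sorted(leaves_seen) != list(range(n)):
            raise ValidationError("leaf set must be exactly 0..n-1")
        for u in leaves_seen:
            if n > 1 and len(self.adj[u]) != 1:
                raise ValidationError(f"leaf {u} must have degree 1")

    # -- identity ----------------------------------------------------------

    def bipartitions(self) -> frozenset[int]:
        """Non-trivial splits as masks of the side not containing taxon 0."""
        if self._key is not None:
            return self._key
        n = self.n_leaves
        full = (1 << n) - 1
        masks: dict[int, int] = {i: 1 << i for i in range(n)}
        splits = set()
        for node, children in _fix_postorder(self):
            m = 0
            for c in children:
                m |= masks[c]
            masks[node] = m
            side = m if not (m & 1) else (full ^ m)
            pop = side.bit_count()
            if 2 <= pop <= n - 2:
                splits.add(side)
        self._key = frozenset(splits)
        return self._key

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.taxa == other.taxa and self.bipartitions() == other.bipartitions()

    def __hash__(self) -> int:
        return hash((self.taxa, self.bipartitions()))

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.taxa,
            {u: set(vs) for u, vs in self.adj.items()},
            clade_support=dict(self.clade_support) if self.clade_support else None,
            edge_lengths=dict(self.edge_lengths) if self.edge_lengths else None,
        )

    def clades(self) -> list[frozenset[str]]:
        """Bipartitions as taxon-name sets (the side not containing taxon 0)."""
        return [
            frozenset(self.taxa[i] for i in range(self.n_leaves) if mask >> i & 1)
            for mask in sorted(self.bipartitions())
        ]

    # -- I/O ---------------------------------------------------------------

    def to_newick(
        self, outgroup: Optional[str] = None, with_annotations: bool = False
    ) -> str:
        return write_newick(self, outgroup=outgroup, with_annotations=with_annotations)

    def __repr__(self) -> str:
        return f"<PhyloTree n={self.n_leaves} splits={len(self.bipartitions())}>"


def _fix_postorder(tree: PhyloTree) -> list[tuple[int, tuple[int, ...]]]:
    """Postorder (node, children-away-from-root) rooted at leaf 0's neighbor.

    Leaf 0 itself is excluded; a caller folding states up the tree must
    finally combine the last node's state with leaf 0's own state.
    """
    if tree.n_leaves < 2:
        return []
    root = next(iter(tree.adj[0]))
    out: list[tuple[int, tuple[int, ...]]] = []
    stack: list[tuple[int, int, bool]] = [(root, 0, False)]
    while stack:
        node, parent, expanded = stack.pop()
        children = tuple(nb for nb in tree.adj[node] if nb != parent)
        if expanded:
            out.append((node, children))
        else:
            stack.append((node, parent, True))
            for c in children:
                if not tree.is_leaf(c):
                    stack.append((c, node, False))
    return out


def postorder_nodes(tree: PhyloTree) -> list[tuple[int, tuple[int, ...]]]:
    """Public alias for the leaf-0-rooted postorder used by length code."""
    return _fix_postorder(tree)


# -- construction from splits -----------------------------------------------


def tree_from_clades(
    taxa: Sequence[str],
    clade_masks: Iterable[int],
    clade_support: Optional[dict[int, float]] = None,
) -> PhyloTree:
    """Build the (possibly polytomous) tree displaying a compatible clade set.

    Masks follow the taxon-0-excluded orientation used throughout; the
    family must be laminar (pairwise nested or disjoint).
    """
    taxa = tuple(taxa)
    n = len(taxa)
    masks = sorted(set(clade_masks), key=lambda m: m.bit_count())
    for i, a in enumerate(masks):
        for b in masks[i + 1:]:
            if a & b and not (a & b == a):
                raise ValidationError("clade set is not compatible")
    universe = ((1 << n) - 1) ^ 1  # all taxa except taxon 0
    node_of: dict[int, int] = {}
    next_id = n
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    node_of[universe] = next_id
    adj[next_id] = set()
    next_id += 1
    for m in masks:
        if m == universe:
            continue
        node_of[m] = next_id
        adj[next_id] = set()
        next_id += 1

    def connect(u: int, v: int) -> None:
        adj[u].add(v)
        adj[v].add(u)

    # parent of a clade: smallest strictly-containing clade (else universe)
    items = masks + [universe] if universe not in masks else masks
    for m in masks:
        if m == universe:
            continue
        candidates = [p for p in items if p != m and (m & p) == m]
        parent = min(candidates, key=lambda p: p.bit_count())
        connect(node_of[m], node_of[parent])
    # each leaf hangs off the smallest clade containing it
    for i in range(1, n):
        bit = 1 << i
        candidates = [p for p in items if p & bit]
        parent = min(candidates, key=lambda p: p.bit_count())
        connect(i, node_of[parent])
    connect(0, node_of[universe])
    return PhyloTree(taxa, adj, clade_support=clade_support)


# -- consensus ---------------------------------------------------------------


def _check_same_taxa(trees: Sequence[PhyloTree]) -> tuple[str, ...]:
    if not trees:
        raise ValidationError("need at least one tree")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise ValidationError("consensus requires identical leaf sets")
    return taxa


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree displaying exactly the clades present in every input tree."""
    taxa = _check_same_taxa(trees)
    common = frozenset.intersection(*(t.bipartitions() for t in trees))
    return tree_from_clades(taxa, common)


def majority_rule(trees: Sequence[PhyloTree], f: float = 0.5) -> PhyloTree:
    """Consensus of clades occurring in strictly more than a fraction f of trees.

    Clade frequencies (percent of input trees) are attached to the result as
    ``clade_support``.  The default f = 0.5 guarantees compatibility.
    """
    if not 0.5 <= f < 1:
        raise ValidationError(f"majority fraction must be in [0.5, 1), got {f}")
    taxa = _check_same_taxa(trees)
    counts: dict[int, int] = {}
    for t in trees:
        for m in t.bipartitions():
            counts[m] = counts.get(m, 0) + 1
    total = len(trees)
    kept = {m: 100.0 * c / total for m, c in counts.items() if c / total > f}
    return tree_from_clades(taxa, kept.keys(), clade_support=kept)


# -- Newick ------------------------------------------------------------------


def write_newick(
    tree: PhyloTree,
    outgroup: Optional[str] = None,
    with_annotations: bool = False,
    branch_lengths: Optional[dict[frozenset[int], float]] = None,
) -> str:
    """Serialize to Newick.

    Unrooted trees are written with an arbitrary basal trifurcation, or
    rooted on ``outgroup`` (outgroup sister to everything else) on request.
    Clade-frequency annotations become internal node labels.
    """
    blens = branch_lengths if branch_lengths is not None else tree.edge_lengths
    support = tree.clade_support if with_annotations else None
    n = tree.n_leaves
    full = (1 << n) - 1
    if n == 1:
        return f"{tree.taxa[0]};"

    if outgroup is not None:
        if outgroup not in tree.taxa:
            raise ValidationError(f"outgroup {outgroup!r} not among taxa")
        og = tree.taxa.index(outgroup)
        start = next(iter(tree.adj[og]))
        start_parent = og
    else:
        og = None
        start = next(iter(tree.adj[0]))
        start_parent = 0

    def label(node: int, below_mask: int) -> str:
        if support is None:
            return ""
        side = below_mask if not (below_mask & 1) else (full ^ below_mask)
        pct = support.get(side)
        return "" if pct is None else f"{pct:g}"

    def blen(u: int, v: int) -> str:
        if blens is None:
            return ""
        val = blens.get(frozenset((u, v)))
        return "" if val is None else f":{val:g}"

    def render(node: int, parent: int) -> tuple[str, int]:
        if tree.is_leaf(node):
            return tree.taxa[node] + blen(node, parent), 1 << node
        parts = []
        mask = 0
        for nb in sorted(tree.adj[node]):
            if nb == parent:
                continue
            text, m = render(nb, node)
            parts.append(text)
            mask |= m
        return (
            "(" + ",".join(parts) + ")" + label(node, mask) + blen(node, parent),
            mask,
        )

    inner, _ = render(start, start_parent)
    first = tree.taxa[og] if outgroup is not None else tree.taxa[start_parent]
    return f"({first}{blen(start_parent if outgroup is None else og, start)},{inner});"


def read_newick(
    text: str, taxa: Optional[Sequence[str]] = None
) -> PhyloTree:
    """Parse a Newick string into a PhyloTree (via dendropy).

    If ``taxa`` is given, leaf ids follow that ordering; otherwise taxa are
    sorted alphabetically.  Internal node labels are interpreted as clade
    frequencies when they parse as numbers.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ParseError(f"malformed newick: {exc}") from exc
    leaf_labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if taxa is None:
        taxa = sorted(leaf_labels)
    if sorted(leaf_labels) != sorted(taxa):
        raise ParseError("newick leaf set does not match expected taxa")
    index = {name: i for i, name in enumerate(taxa)}
    n = len(taxa)
    full = (1 << n) - 1

    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    next_id = [n]
    support: dict[int, float] = {}
    blens: dict[frozenset[int], float] = {}
    any_blen = [False]

    def connect(u: int, v: int, length) -> None:
        adj[u].add(v)
        adj[v].add(u)
        if length is not None:
            blens[frozenset((u, v))] = float(length)
            any_blen[0] = True

    def build(node) -> tuple[int, int]:
        if node.is_leaf():
            i = index[node.taxon.label]
            return i, 1 << i
        me = next_id[0]
        next_id[0] += 1
        adj[me] = set()
        mask = 0
        for child in node.child_nodes():
            cid, cmask = build(child)
            connect(me, cid, child.edge.length)
            mask |= cmask
        if node.label is not None:
            try:
                side = mask if not (mask & 1) else (full ^ mask)
                support[side] = float(node.label)
            except ValueError:
                pass
        return me, mask

    root = dtree.seed_node
    kids = root.child_nodes()
    if len(kids) == 2:
        # rooted binary newick: suppress the root to recover the unrooted tree
        a_id, _ = build(kids[0])
        b_id, _ = build(kids[1])
        la = kids[0].edge.length or 0.0
        lb = kids[1].edge.length or 0.0
        connect(a_id, b_id, (la + lb) if (kids[0].edge.length is not None or kids[1].edge.length is not None) else None)
    else:
        me = next_id[0]
        next_id[0] += 1
        adj[me] = set()
        for child in kids:
            cid, _ = build(child)
            connect(me, cid, child.edge.length)
    # drop any degree-2 internal nodes left over
    changed = True
    while changed:
        changed = False
        for u in list(adj):
            if u >= n and len(adj[u]) == 2:
                a, b = sorted(adj[u])
                la = blens.pop(frozenset((u, a)), None)
                lb = blens.pop(frozenset((u, b)), None)
                adj[a].discard(u)
                adj[b].discard(u)
                del adj[u]
                connect(a, b, (la or 0.0) + (lb or 0.0) if any_blen[0] else None)
                changed = True
    return PhyloTree(
        tuple(taxa),
        adj,
        clade_support=support or None,
        edge_lengths=blens if any_blen[0] else None,
    )
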