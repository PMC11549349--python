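"""Stratigraphically time-calibrated trees.

A consensus topology is turned into a chronogram by minimum-age
calibration: every tip is drawn at its first appearance datum (FAD, in Ma
before present; larger = older), and every internal node takes the age of
its oldest descendant tip, optionally plus a uniform padding at the root.
Zero-length internal edges are permitted.  The ghost lineage of a tip is
the implied-but-unsampled interval between its parent's age and its own
FAD.  The FAD-LAD range is carried along as metadata for rendering.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from paleosnake.errors import ValidationError
from paleosnake.parsimony.tree import PhyloTree, postorder_nodes


@dataclass(frozen=True)
class StratRange:
    """First/last appearance of a taxon in the fossil record (Ma)."""

    taxon: str
    fad_ma: float
    lad_ma: float

    def __post_init__(self) -> None:
        if not self.fad_ma >= self.lad_ma > 0:
            raise ValidationError(
                f"{self.taxon}: need fad >= lad > 0, got fad={self.fad_ma}, "
                f"lad={self.lad_ma}"
            )


def read_ranges_csv(path: str | Path) -> list[StratRange]:
    ranges = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(line for line in fh if not line.startswith("#"))
        for row in reader:
            ranges.append(
                StratRange(
                    taxon=row["taxon"],
                    fad_ma=float(row["fad_ma"]),
                    lad_ma=float(row["lad_ma"]),
                )
            )
    return ranges


def write_ranges_csv(ranges: Sequence[StratRange], path: str | Path,
                     header_comment: str = "") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(["taxon", "fad_ma", "lad_ma"])
        for r in ranges:
            writer.writerow([r.taxon, r.fad_ma, r.lad_ma])


@dataclass
class TimeTree:
    """A topology whose nodes carry ages in Ma and tips ghost lineages."""

    topology: PhyloTree
    root: int
    node_age: dict[int, float]
    ghost_lineage: dict[str, float]
    parent: dict[int, int]
    children: dict[int, list[int]] = field(default_factory=dict)
    ranges: dict[str, StratRange] = field(default_factory=dict)

    def age_of(self, node: int) -> float:
        return self.node_age[node]

    def to_newick(self) -> str:
        """Newick with branch lengths in Myr (parent age minus child age)."""
        tree = self.topology

        def render(node: int) -> str:
            kids = self.children.get(node, [])
            if not kids:
                label = tree.taxa[node]
            else:
                label = "(" + ",".join(render(c) for c in kids) + ")"
            if node == self.root:
                return label
            blen = self.node_age[self.parent[node]] - self.node_age[node]
            return f"{label}:{blen:g}"

        return render(self.root) + ";"

    def node_age_table(self) -> dict:
        tree = self.topology
        entries = []
        for node, age in sorted(self.node_age.items()):
            entry: dict[str, object] = {"node": node, "age_ma": age}
            if tree.is_leaf(node):
                entry["taxon"] = tree.taxa[node]
                entry["ghost_lineage_myr"] = self.ghost_lineage[tree.taxa[node]]
                rng = self.ranges.get(tree.taxa[node])
                if rng is not None:
                    entry["fad_ma"], entry["lad_ma"] = rng.fad_ma, rng.lad_ma
            entries.append(entry)
        return {
            "calibration": "minimum-age (node = oldest descendant FAD)",
            "nodes": entries,
        }

    def to_json(self) -> str:
        return json.dumps(self.node_age_table(), indent=2)


def calibrate(
    tree: PhyloTree,
    ranges: Sequence[StratRange],
    root_padding_myr: float = 0.0,
    outgroup: Optional[str] = None,
) -> TimeTree:
    """Minimum-age calibration of a tree from tip stratigraphic ranges.

    The tree is rooted at ``outgroup`` (or the tree's first taxon when not
    given); each node's age is the maximum FAD among its descendant tips,
    with ``root_padding_myr`` added at the root only.
    """
    if root_padding_myr < 0:
        raise ValidationError("root_padding_myr must be >= 0")
    by_taxon = {r.taxon: r for r in ranges}
    missing = [t for t in tree.taxa if t not in by_taxon]
    if missing:
        raise ValidationError(f"missing stratigraphic ranges for tips: {missing}")

    anchor = outgroup if outgroup is not None else tree.taxa[0]
    if anchor not in tree.taxa:
        raise ValidationError(f"outgroup {anchor!r} not among taxa")
    anchor_id = tree.taxa.index(anchor)
    # root the tree on the edge leading to the anchor tip: a new bifurcating
    # root joins the anchor and the rest of the tree
    basal = next(iter(tree.adj[anchor_id]))
    root = max(tree.adj) + 1

    parent: dict[int, int] = {anchor_id: root, basal: root, root: -1}
    children: dict[int, list[int]] = {root: [anchor_id, basal]}
    order: list[int] = [basal]
    stack = [(basal, anchor_id)]
    while stack:
        node, par = stack.pop()
        kids = [nb for nb in tree.adj[node] if nb != par]
        children[node] = kids
        for nb in kids:
            parent[nb] = node
            order.append(nb)
            stack.append((nb, node))

    node_age: dict[int, float] = {}
    for node in reversed(order):
        if tree.is_leaf(node):
            node_age[node] = by_taxon[tree.taxa[node]].fad_ma
        else:
            node_age[node] = max(node_age[c] for c in children[node])
    node_age[anchor_id] = by_taxon[anchor].fad_ma
    node_age[root] = (
        max(node_age[basal], node_age[anchor_id]) + root_padding_myr
    )

    ghost = {}
    for i, taxon in enumerate(tree.taxa):
        ghost[taxon] = node_age[parent[i]] - node_age[i]
    return TimeTree(
        topology=tree,
        root=root,
        node_age=node_age,
        ghost_lineage=ghost,
        parent=parent,
        children=children,
        ranges=by_taxon,
    )
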