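"""Relative node ages on ultrametric (relaxed-clock) trees.

The age of a clade is the height of its MRCA above the leaves; the ratio
of two clade ages is a unit-free relative chronology. Optional 95%
intervals on node heights propagate to an interval on the ratio as
[low_old / high_young, high_old / low_young].
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

import dendropy

__all__ = ["UltrametricTree", "node_age_ratio", "read_ultrametric_tree"]

_REL_TOL = 1e-6

_HEIGHT_HPD_RE = re.compile(
    r"height_95%?_?HPD=\{([0-9eE.+-]+),([0-9eE.+-]+)\}"
)


class ChronologyError(ValueError):
    pass


@dataclass
class UltrametricTree:
    tree: dendropy.Tree
    #: optional (low, high) height interval per node, keyed by the frozenset
    #: of descendant leaf labels
    intervals: dict[frozenset, tuple[float, float]]

    @property
    def taxa(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def mrca_height(self, taxa: set[str]) -> float:
        node = self._mrca(taxa)
        return _node_height(node)

    def mrca_interval(self, taxa: set[str]) -> tuple[float, float] | None:
        node = self._mrca(taxa)
        key = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        return self.intervals.get(key)

    def _mrca(self, taxa: set[str]):
        unknown = set(taxa) - self.taxa
        if unknown:
            raise ChronologyError(f"taxa not in tree: {sorted(unknown)}")
        node = self.tree.mrca(taxon_labels=sorted(taxa))
        if node is None:
            raise ChronologyError(f"no MRCA for {sorted(taxa)}")
        return node


def _node_height(node) -> float:
    """Distance from a node down to its leaves (ultrametric: all equal)."""
    if node.is_leaf():
        return 0.0
    child = node.child_nodes()[0]
    return (child.edge.length or 0.0) + _node_height(child)


def _check_ultrametric(tree: dendropy.Tree) -> None:
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    if not depths:
        raise ChronologyError("tree has no leaves")
    dmax = max(depths)
    if dmax == 0:
        raise ChronologyError("tree has zero depth")
    if (dmax - min(depths)) / dmax > _REL_TOL:
        raise ChronologyError(
            f"tree is not ultrametric (leaf depths {min(depths)}..{dmax})"
        )


def _parse_comment_intervals(tree: dendropy.Tree) -> dict[frozenset, tuple[float, float]]:
    intervals: dict[frozenset, tuple[float, float]] = {}
    for node in tree.preorder_node_iter():
        for comment in node.comments or []:
            m = _HEIGHT_HPD_RE.search(comment)
            if m:
                key = frozenset(
                    leaf.taxon.label for leaf in node.leaf_iter()
                )
                intervals[key] = (float(m.group(1)), float(m.group(2)))
    return intervals


def read_ultrametric_tree(
    path: str | Path, intervals_tsv: str | Path | None = None
) -> UltrametricTree:
    """Read a Newick tree; node-height 95% intervals come from BEAST-style
    ``[&height_95%_HPD={low,high}]`` comments or a sidecar TSV with columns
    ``taxa`` (comma-separated leaf labels), ``low``, ``high``."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        extract_comment_metadata=False,
        rooting="force-rooted",
    )
    _check_ultrametric(tree)
    intervals = _parse_comment_intervals(tree)
    if intervals_tsv is not None:
        with open(intervals_tsv, encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                taxa = frozenset(t.strip() for t in row["taxa"].split(","))
                node = tree.mrca(taxon_labels=sorted(taxa))
                if node is None:
                    raise ChronologyError(f"no MRCA for sidecar clade {sorted(taxa)}")
                key = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
                intervals[key] = (float(row["low"]), float(row["high"]))
    return UltrametricTree(tree=tree, intervals=intervals)


def node_age_ratio(
    tree: UltrametricTree,
    clade_old: set[str],
    clade_young: set[str],
) -> tuple[float, tuple[float, float] | None]:
    """height(MRCA(old)) / height(MRCA(young)), plus an interval ratio when
    both nodes carry height intervals."""
    h_old = tree.mrca_height(set(clade_old))
    h_young = tree.mrca_height(set(clade_young))
    if h_young == 0:
        raise ChronologyError("young clade MRCA has zero height")
    ratio = h_old / h_young
    iv_old = tree.mrca_interval(set(clade_old))
    iv_young = tree.mrca_interval(set(clade_young))
    interval = None
    if iv_old is not None and iv_young is not None and iv_young[1] > 0 and iv_young[0] > 0:
        interval = (iv_old[0] / iv_young[1], iv_old[1] / iv_young[0])
    return ratio, interval
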