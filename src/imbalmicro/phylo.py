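"""Rooted phylogeny over the taxa, backed by dendropy.

The tree's leaves must map bijectively onto the abundance table's taxon ids;
the phylogeny-aware augmenter walks it root-to-leaves. Internal node labels
and (by default) branch lengths carry no meaning for the augmenter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

__all__ = ["PhyloTree"]


@dataclass
class _Node:
    """Flattened tree node used for fast top-down traversal."""

    children: list[int]  # indices into the node list; empty for leaves
    leaf_index: int  # column index of the taxon for leaves, -1 otherwise
    leaf_set: np.ndarray  # column indices of all descendant leaves
    branch_length: float


class PhyloTree:
    """Rooted tree whose leaves are taxa.

    Wraps a :class:`dendropy.Tree` and precomputes, per node, the set of
    descendant-leaf column indices relative to a fixed taxon ordering — the
    structure the generative augmenter needs at every split.
    """

    def __init__(self, tree: dendropy.Tree):
        if tree.seed_node is None:
            raise ValueError("tree has no root")
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise ValueError("every leaf must carry a taxon label")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")
        self._leaf_labels = labels
        self._nodes: list[_Node] | None = None
        self._indexed_taxa: list[str] | None = None

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        path = Path(source)
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def from_newick_string(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", unquoted_underscores=True)

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick(), encoding="utf-8")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaf_labels)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    def prune_to(self, taxon_ids: list[str]) -> "PhyloTree":
        """Restrict the tree to the given leaves (e.g. after taxon filters)."""
        self.validate_taxa(list(taxon_ids))
        if set(taxon_ids) == set(self._leaf_labels):
            return self
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(list(taxon_ids))
        return PhyloTree(clone)

    def validate_taxa(self, taxon_ids: list[str]) -> None:
        """Require the leaf-label set to cover every table taxon."""
        missing = sorted(set(taxon_ids) - set(self._leaf_labels))
        if missing:
            raise ValueError(f"taxa missing from tree: {missing}")

    def indexed_nodes(self, taxon_ids: list[str]) -> list[_Node]:
        """Flattened preorder node list with leaf columns matching taxon_ids.

        Node 0 is the root; children indices always exceed the parent's, so a
        single forward pass is a valid top-down traversal.
        """
        if self._nodes is not None and self._indexed_taxa == list(taxon_ids):
            return self._nodes
        self.validate_taxa(taxon_ids)
        extra = sorted(set(self._leaf_labels) - set(taxon_ids))
        if extra:
            raise ValueError(f"tree has leaves absent from the table: {extra}")
        col = {t: i for i, t in enumerate(taxon_ids)}

        nodes: list[_Node] = []
        index_of: dict[int, int] = {}
        for nd in self._tree.preorder_node_iter():
            idx = len(nodes)
            index_of[id(nd)] = idx
            bl = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                leaf_idx = col[nd.taxon.label]
                nodes.append(
                    _Node([], leaf_idx, np.array([leaf_idx], dtype=np.intp), bl)
                )
            else:
                nodes.append(_Node([], -1, np.empty(0, dtype=np.intp), bl))
            parent = nd.parent_node
            if parent is not None:
                nodes[index_of[id(parent)]].children.append(idx)
        # fill descendant-leaf sets bottom-up
        for idx in range(len(nodes) - 1, -1, -1):
            nd = nodes[idx]
            if nd.children:
                nd.leaf_set = np.concatenate([nodes[c].leaf_set for c in nd.children])
        self._nodes = nodes
        self._indexed_taxa = list(taxon_ids)
        return nodes
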