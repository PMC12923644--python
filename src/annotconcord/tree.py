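"""Rooted trees with optional branch lengths and unique leaf labels.

Newick reading and writing delegate to dendropy; the in-memory form is a
minimal node structure that the selection and split algorithms traverse
directly. Taxonomy trees carry integer branch lengths (the number of
taxonomic levels a branch spans); phylogenies carry real-valued lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional

import dendropy

from .model import ParseError

__all__ = ["TreeNode", "PhyloTree", "parse_newick", "write_newick"]


@dataclass
class TreeNode:
    label: Optional[str] = None
    length: Optional[float] = None  # branch to the parent; None for the root
    children: List["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree. Leaf labels must be unique and non-empty."""

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [leaf.label for leaf in self.leaves()]
        if any(not lb for lb in labels):
            raise ValueError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        self._leaf_index = {leaf.label: leaf for leaf in self.leaves()}

    def nodes(self) -> Iterator[TreeNode]:
        """Preorder traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator[TreeNode]:
        for node in self.nodes():
            if node.is_leaf:
                yield node

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(self._leaf_index)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_index)

    def leaf(self, label: str) -> TreeNode:
        try:
            return self._leaf_index[label]
        except KeyError:
            raise KeyError(f"no leaf labelled {label!r} in tree") from None

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes() if n.length is not None)

    def to_newick(self) -> str:
        return write_newick(self)


def _from_dendropy(node: dendropy.Node) -> TreeNode:
    label = node.taxon.label if node.taxon is not None else node.label
    out = TreeNode(label=label, length=node.edge.length)
    for child in node.child_nodes():
        out.add_child(_from_dendropy(child))
    return out


def parse_newick(text: str) -> PhyloTree:
    """Parse a single newick tree. Absent branch lengths stay absent (None),
    never coerced to zero."""
    if not text or not text.strip():
        raise ParseError("empty newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"newick parse failed: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = None  # the root has no incoming edge
    try:
        return PhyloTree(root)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def _to_dendropy(node: TreeNode, dtree: dendropy.Tree, dnode: dendropy.Node) -> None:
    if node.is_leaf:
        dnode.taxon = dtree.taxon_namespace.new_taxon(label=node.label)
    elif node.label:
        dnode.label = node.label
    dnode.edge.length = node.length
    for child in node.children:
        dchild = dendropy.Node()
        dnode.add_child(dchild)
        _to_dendropy(child, dtree, dchild)


def write_newick(tree: PhyloTree) -> str:
    dtree = dendropy.Tree()
    _to_dendropy(tree.root, dtree, dtree.seed_node)
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return text.strip() + "\n"
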