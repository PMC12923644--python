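"""Maximum-diversity leaf selection on a taxonomy tree.

The objective of a leaf set is the total branch length of the induced
subtree: the union of the root-to-leaf edge paths, each edge counted once.
For trees derived from a rank hierarchy the branch lengths are the integer
number of taxonomic levels each branch spans, but any non-negative lengths
are accepted. Mandatory "anchor" leaves are included first; the remaining
picks greedily maximize the marginal gain. On trees this objective is
monotone and submodular, and the greedy choice is exact (verified against
exhaustive enumeration in the tests), so the greedy result is the optimum.

Ties are broken by lexicographically smallest leaf label so runs are
reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, List, Set

from .tree import PhyloTree, TreeNode

__all__ = [
    "SelectionResult",
    "induced_subtree_length",
    "select_max_diversity",
    "brute_force_select",
]

BRUTE_FORCE_LEAF_GUARD = 20


@dataclass
class SelectionResult:
    selected: List[str]  # anchors first, then greedy additions in pick order
    total_length: float
    gains: List[float]  # marginal gain of each step, aligned with `selected`


def _require_length(node: TreeNode) -> float:
    if node.length is None:
        raise ValueError(
            f"branch above {node.label or '<internal>'} has no length; "
            "the selection objective needs a length on every edge"
        )
    return node.length


def induced_subtree_length(tree: PhyloTree, leaves: Iterable[str]) -> float:
    """Total branch length of the union of root paths of ``leaves``."""
    labels = set(leaves)
    if not labels:
        raise ValueError("need at least one leaf")
    covered: Set[int] = set()
    total = 0.0
    for label in labels:
        node = tree.leaf(label)  # raises KeyError for unknown labels
        while node.parent is not None and id(node) not in covered:
            total += _require_length(node)
            covered.add(id(node))
            node = node.parent
    return total


def _marginal_gain(tree: PhyloTree, label: str, covered: Set[int]) -> float:
    node = tree.leaf(label)
    gain = 0.0
    while node.parent is not None and id(node) not in covered:
        gain += _require_length(node)
        node = node.parent
    return gain


def _cover(tree: PhyloTree, label: str, covered: Set[int]) -> None:
    node = tree.leaf(label)
    while node.parent is not None and id(node) not in covered:
        covered.add(id(node))
        node = node.parent


def select_max_diversity(
    tree: PhyloTree, anchors: Iterable[str], n: int
) -> SelectionResult:
    """Pick ``n`` leaves (anchors included) maximizing induced subtree length.

    Greedy: anchors enter first (sorted); each further step adds the leaf
    with the largest marginal gain, smallest label on ties.
    """
    anchor_set = set(anchors)
    all_leaves = tree.leaf_labels
    unknown = anchor_set - all_leaves
    if unknown:
        raise ValueError(f"anchors not in tree: {sorted(unknown)}")
    if len(anchor_set) > n:
        raise ValueError(f"{len(anchor_set)} anchors exceed n={n}")
    if n > len(all_leaves):
        raise ValueError(f"n={n} exceeds leaf count {len(all_leaves)}")

    covered: Set[int] = set()
    selected: List[str] = []
    gains: List[float] = []
    total = 0.0
    for label in sorted(anchor_set):
        gain = _marginal_gain(tree, label, covered)
        _cover(tree, label, covered)
        selected.append(label)
        gains.append(gain)
        total += gain

    candidates = sorted(all_leaves - anchor_set)
    while len(selected) < n:
        best_label, best_gain = None, -1.0
        for label in candidates:
            gain = _marginal_gain(tree, label, covered)
            if gain > best_gain:
                best_label, best_gain = label, gain
        assert best_label is not None
        candidates.remove(best_label)
        _cover(tree, best_label, covered)
        selected.append(best_label)
        gains.append(best_gain)
        total += best_gain
    return SelectionResult(selected=selected, total_length=total, gains=gains)


def brute_force_select(
    tree: PhyloTree, anchors: Iterable[str], n: int
) -> SelectionResult:
    """Exact optimum by exhausting all C(leaves, n) subsets (test oracle).

    Guarded to small trees; ties resolved toward the lexicographically
    smallest sorted label tuple.
    """
    anchor_set = set(anchors)
    all_leaves = tree.leaf_labels
    if len(all_leaves) > BRUTE_FORCE_LEAF_GUARD:
        raise ValueError(
            f"brute force is limited to {BRUTE_FORCE_LEAF_GUARD} leaves; "
            "use select_max_diversity"
        )
    unknown = anchor_set - all_leaves
    if unknown:
        raise ValueError(f"anchors not in tree: {sorted(unknown)}")
    if len(anchor_set) > n:
        raise ValueError(f"{len(anchor_set)} anchors exceed n={n}")
    if n > len(all_leaves):
        raise ValueError(f"n={n} exceeds leaf count {len(all_leaves)}")

    free = sorted(all_leaves - anchor_set)
    best_tuple = None
    best_length = float("-inf")
    for combo in itertools.combinations(free, n - len(anchor_set)):
        labels = tuple(sorted(anchor_set | set(combo)))
        length = induced_subtree_length(tree, labels) if labels else 0.0
        if length > best_length or (length == best_length and labels < best_tuple):
            best_tuple, best_length = labels, length
    return SelectionResult(
        selected=list(best_tuple), total_length=best_length, gains=[]
    )
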