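"""Split-based comparison of two trees on the same leaf set.

Trees are compared unrooted (a degree-2 root is suppressed implicitly by the
canonical split form). Only non-trivial bipartitions — both sides with at
least two leaves — are considered. Two shared-split fractions are reported
because published "X% of splits are shared" statements rarely name their
denominator:

``shared_fraction_sum``
    2·|S1 ∩ S2| / (|S1| + |S2|), the complement of the classic normalized
    Robinson-Foulds distance.
``shared_fraction_union``
    |S1 ∩ S2| / |S1 ∪ S2|, a Jaccard index on split sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Optional, Set, Tuple

from .tree import PhyloTree, TreeNode

__all__ = ["SplitSet", "TreeComparison", "bipartitions", "shared_split_stats"]

Split = Tuple[str, ...]


@dataclass(frozen=True)
class SplitSet:
    leaf_universe: FrozenSet[str]
    splits: FrozenSet[Split]  # each split = the sorted side without the
    # lexicographically smallest leaf of the universe


@dataclass(frozen=True)
class TreeComparison:
    rf: int
    shared_fraction_sum: float
    shared_fraction_union: float
    n_splits_1: int
    n_splits_2: int
    n_shared: int


def _leafsets(root: TreeNode) -> Dict[int, FrozenSet[str]]:
    out: Dict[int, FrozenSet[str]] = {}

    def visit(node: TreeNode) -> FrozenSet[str]:
        if node.is_leaf:
            ls = frozenset([node.label])
        else:
            ls = frozenset().union(*(visit(c) for c in node.children))
        out[id(node)] = ls
        return ls

    visit(root)
    return out


def _canonical(side: FrozenSet[str], universe: FrozenSet[str], ref: str) -> Split:
    if ref in side:
        side = universe - side
    return tuple(sorted(side))


def bipartitions(
    tree: PhyloTree, restrict_to: Optional[FrozenSet[str]] = None
) -> SplitSet:
    """Non-trivial splits of the unrooted form of ``tree``.

    ``restrict_to`` restricts the universe to a leaf subset first (splits are
    intersected with it and re-filtered), which is how prune-to-common
    comparison works. Multifurcations simply yield fewer splits.
    """
    universe = tree.leaf_labels
    if restrict_to is not None:
        universe = universe & restrict_to
    if len(universe) < 4:
        raise ValueError(
            f"need at least 4 leaves for non-trivial splits, got {len(universe)}"
        )
    ref = min(universe)
    leafsets = _leafsets(tree.root)
    splits: Set[Split] = set()
    for node in tree.nodes():
        if node.parent is None or node.is_leaf:
            continue
        side = leafsets[id(node)] & universe
        if 2 <= len(side) <= len(universe) - 2:
            splits.add(_canonical(side, universe, ref))
    return SplitSet(leaf_universe=frozenset(universe), splits=frozenset(splits))


def shared_split_stats(
    tree1: PhyloTree, tree2: PhyloTree, pruning: str = "strict"
) -> TreeComparison:
    """Robinson-Foulds distance and shared-split fractions of two trees.

    ``strict`` requires identical leaf sets; ``prune_to_common`` restricts
    both trees to their shared leaves first.
    """
    l1, l2 = tree1.leaf_labels, tree2.leaf_labels
    if pruning == "strict":
        if l1 != l2:
            raise ValueError(
                "leaf sets differ: only in tree1 "
                f"{sorted(l1 - l2)}, only in tree2 {sorted(l2 - l1)}"
            )
        common = None
    elif pruning == "prune_to_common":
        common = frozenset(l1 & l2)
    else:
        raise ValueError(f"unknown pruning mode {pruning!r}")

    s1 = bipartitions(tree1, restrict_to=common).splits
    s2 = bipartitions(tree2, restrict_to=common).splits
    shared = len(s1 & s2)
    union = len(s1 | s2)
    denom_sum = len(s1) + len(s2)
    return TreeComparison(
        rf=len(s1 ^ s2),
        shared_fraction_sum=2 * shared / denom_sum if denom_sum else 1.0,
        shared_fraction_union=shared / union if union else 1.0,
        n_splits_1=len(s1),
        n_splits_2=len(s2),
        n_shared=shared,
    )
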