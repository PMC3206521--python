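"""Tree-to-tree distances used to score CGH trees against the MLSA tree.

Two metrics: the symmetric (Robinson-Foulds) distance ``SymD`` — the
number of nontrivial splits present in exactly one of the two unrooted
topologies — and the agreement-subtree distance ``D1`` — the minimum
number of taxa that must be pruned so the two restricted topologies
become identical.  Identical topologies score 0 under both; collapsing
one internal branch of a binary tree costs 1 SymD step and swapping two
taxa costs 2.

Both metrics operate on the shared leaf set: when one tree carries extra
taxa (e.g. the reference taxon in a ±reference comparison) the trees are
restricted to the intersection first.
"""

from __future__ import annotations

import itertools
import logging

from .io import Tree, _canonical

log = logging.getLogger(__name__)

__all__ = ["restrict_tree", "symmetric_distance", "agreement_subtree_distance"]


def restrict_tree(tree: Tree, keep) -> Tree:
    """Prune ``tree`` to the leaf subset ``keep``.

    Degree-2 nodes created by pruning are suppressed; when the tree has
    branch lengths, the lengths of edges merged into one restricted edge
    are summed, so leaf-to-leaf path lengths are preserved.
    """
    keep = frozenset(keep)
    if not keep <= tree.leaves:
        raise ValueError(f"taxa not in tree: {sorted(keep - tree.leaves)}")
    if len(keep) < 3:
        raise ValueError("restriction needs at least 3 taxa")
    if keep == tree.leaves:
        return tree

    def project(side: frozenset):
        """Restricted edge key for an original edge, or None if trivial."""
        a = side & keep
        b = keep - a
        if not a or not b:
            return None
        small, big = (a, b) if len(a) <= len(b) else (b, a)
        if len(small) == 1:
            return next(iter(small))  # pendant edge of the restriction
        return _canonical(a, keep)

    new_splits = set()
    lengths: dict | None = {} if tree.branch_lengths is not None else None
    edges = [(frozenset([lf]), lf) for lf in tree.leaves]
    edges += [(s, s) for s in tree.splits]
    for side, key in edges:
        proj = project(side if isinstance(side, frozenset) else frozenset([side]))
        if proj is None:
            continue
        if isinstance(proj, frozenset):
            new_splits.add(proj)
        if lengths is not None:
            lengths[proj] = lengths.get(proj, 0.0) + tree.branch_lengths.get(key, 0.0)
    return Tree(leaves=keep, splits=frozenset(new_splits), branch_lengths=lengths)


def _shared(a: Tree, b: Tree) -> tuple[Tree, Tree]:
    if a.leaves == b.leaves:
        return a, b
    common = a.leaves & b.leaves
    if len(common) < 3:
        raise ValueError("fewer than 3 shared taxa between trees")
    log.info("restricting comparison to %d shared taxa", len(common))
    return restrict_tree(a, common), restrict_tree(b, common)


def symmetric_distance(a: Tree, b: Tree) -> int:
    """Robinson-Foulds symmetric difference of nontrivial split sets.

    Branch lengths are ignored; trees may be multifurcating (a consensus
    tree's missing splits naturally count one step each).
    """
    a, b = _shared(a, b)
    return len(a.splits ^ b.splits)


def agreement_subtree_distance(a: Tree, b: Tree) -> int:
    """Minimum number of leaves to prune to make the topologies identical.

    Computed exactly by enumerating deletion subsets in increasing size;
    feasible at the study's scale (≤9 taxa).  0 iff the topologies are
    already identical; at most n − 3 since any 3-leaf unrooted topology
    is unique.
    """
    a, b = _shared(a, b)
    leaves = sorted(a.leaves)
    n = len(leaves)
    for k in range(0, n - 2):
        for drop in itertools.combinations(leaves, k):
            kept = a.leaves - frozenset(drop)
            if len(kept) < 3:
                continue
            ra = a if not drop else restrict_tree(a, kept)
            rb = b if not drop else restrict_tree(b, kept)
            if ra.splits == rb.splits:
                return k
    return n - 3
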