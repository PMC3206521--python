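"""Tree inference: Neighbor-Joining and Fitch parsimony.

Neighbor-Joining follows Saitou-Nei with the Studier-Keppler Q
criterion; negative branch-length estimates are floored at zero with the
slack moved to the sister edge, so path lengths through a join are
preserved where possible.

Parsimony uses the two-state Fitch/Sankoff dynamic program (exact on
multifurcating trees, missing calls treated as wildcards) inside a
heuristic search: random stepwise-addition starting trees hill-climbed
by nearest-neighbor interchange, with subtree-prune-regraft moves tried
when NNI stalls.  At the study's taxon counts (≤9) an exhaustive search
over all unrooted topologies is feasible and is provided as
``exact=True``; it doubles as the correctness oracle for the heuristic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Tree, _canonical

__all__ = [
    "TreeSet",
    "neighbor_joining",
    "fitch_score",
    "parsimony_search",
    "majority_rule_consensus",
    "enumerate_topologies",
]

_BIG = np.int64(10 ** 9)


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------


def _as_frame(d) -> pd.DataFrame:
    df = getattr(d, "matrix", d)
    if not isinstance(df, pd.DataFrame):
        raise TypeError("expected a DistanceMatrix or a labelled DataFrame")
    return df


def neighbor_joining(d) -> Tree:
    """Saitou-Nei NJ on a taxon x taxon distance matrix.

    Returns an unrooted binary tree with branch lengths.  Accepts a
    :class:`~cghphylo.distance.DistanceMatrix` or a square labelled
    DataFrame.  Requires at least 3 taxa.
    """
    df = _as_frame(d)
    taxa = list(df.index)
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if list(df.columns) != taxa:
        df = df.loc[taxa, taxa]
    dist = df.to_numpy(float).copy()
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix is not symmetric")

    leaves = frozenset(taxa)
    clusters: list[frozenset] = [frozenset([t]) for t in taxa]
    lengths: dict = {}
    splits: set = set()

    def edge_key(cluster: frozenset):
        if len(cluster) == 1:
            return next(iter(cluster))
        return _canonical(cluster, leaves)

    def add_edge(cluster: frozenset, length: float):
        key = edge_key(cluster)
        if isinstance(key, frozenset):
            splits.add(key)
        lengths[key] = lengths.get(key, 0.0) + length

    while len(clusters) > 3:
        n = len(clusters)
        r = dist.sum(axis=1)
        q = (n - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        dij = dist[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        # floor negative estimates, moving the slack to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        add_edge(clusters[i], li)
        add_edge(clusters[j], lj)
        merged = clusters[i] | clusters[j]
        dnew = 0.5 * (dist[i] + dist[j] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        dist = np.vstack([dist[keep][:, keep], dnew[keep][None, :]])
        dist = np.hstack([dist, np.append(dnew[keep], 0.0)[:, None]])
        clusters = [clusters[k] for k in keep] + [merged]

    if len(clusters) == 3:
        d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
        l0 = max(0.0, 0.5 * (d01 + d02 - d12))
        l1 = max(0.0, 0.5 * (d01 + d12 - d02))
        l2 = max(0.0, 0.5 * (d02 + d12 - d01))
        for cl, ln in zip(clusters, (l0, l1, l2)):
            add_edge(cl, ln)
    return Tree(leaves=leaves, splits=frozenset(splits), branch_lengths=lengths)


# ---------------------------------------------------------------------------
# Fitch / two-state Sankoff scoring
# ---------------------------------------------------------------------------


def _character_matrix(binary) -> pd.DataFrame:
    return getattr(binary, "calls", binary)


def _patterns(df: pd.DataFrame, taxa: list):
    """Collapse characters to unique site patterns with multiplicities.

    Returns (states, weights): states is an int8 array of shape
    (n_taxa, n_patterns) with 0/1 calls and 2 for missing.
    """
    arr = df.loc[taxa].to_numpy(float).T  # genes x taxa
    codes = np.where(np.isnan(arr), 2, arr).astype(np.int8)
    uniq, counts = np.unique(codes, axis=0, return_counts=True)
    return uniq.T.copy(), counts.astype(np.int64)


def _score_patterns(adj: dict, leaf_of: dict, states: np.ndarray, weights: np.ndarray) -> int:
    """Minimum-change score summed over weighted patterns (unit costs)."""
    n_pat = states.shape[1]
    # any leaf present in the (possibly partial) tree works as the root
    root = next(v for v in adj if v in leaf_of and adj[v])
    order = []
    parent = {root: None}
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adj[v]:
            if w != parent[v]:
                parent[w] = v
                stack.append(w)
    cost = {}
    for v in reversed(order):
        if v in leaf_of:
            s = states[leaf_of[v]]
            c0 = np.where(s == 1, _BIG, 0)
            c1 = np.where(s == 0, _BIG, 0)
            if v != root:
                cost[v] = (c0, c1)
                continue
            children = [w for w in adj[v] if w != parent[v]]
            for w in children:
                w0, w1 = cost.pop(w)
                c0 = c0 + np.minimum(w0, w1 + 1)
                c1 = c1 + np.minimum(w1, w0 + 1)
            cost[v] = (c0, c1)
        else:
            c0 = np.zeros(n_pat, dtype=np.int64)
            c1 = np.zeros(n_pat, dtype=np.int64)
            for w in adj[v]:
                if w == parent[v]:
                    continue
                w0, w1 = cost.pop(w)
                c0 = c0 + np.minimum(w0, w1 + 1)
                c1 = c1 + np.minimum(w1, w0 + 1)
            cost[v] = (c0, c1)
    c0, c1 = cost[root]
    per_pattern = np.minimum(c0, c1)
    return int(per_pattern @ weights)


def fitch_score(tree: Tree, binary) -> int:
    """Parsimony score of ``tree`` on a taxon x gene 0/1 matrix.

    Missing calls are wildcards (fit any state at no cost); characters
    are summed.  Exact on multifurcating trees via the two-state
    Sankoff recursion.
    """
    df = _character_matrix(binary)
    missing = tree.leaves - set(df.index)
    if missing:
        raise ValueError(f"taxa absent from character matrix: {sorted(missing)}")
    taxa = sorted(tree.leaves)
    adj, leaf_of = _tree_to_adjacency(tree, taxa)
    states, weights = _patterns(df, taxa)
    return _score_patterns(adj, leaf_of, states, weights)


def _tree_to_adjacency(tree: Tree, taxa: list):
    """Node/edge form of a split-set tree (internal nodes are fresh ints)."""
    index = {t: i for i, t in enumerate(taxa)}
    anchor = min(tree.leaves)
    sets = sorted(tree.splits, key=len, reverse=True)
    adj: dict = {i: set() for i in range(len(taxa))}
    counter = itertools.count(len(taxa))

    def connect(a, b):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def build(members: frozenset, available: list) -> int:
        node = next(counter)
        maximal = []
        for s in available:
            if s <= members and not any(s < m for m in maximal):
                maximal.append(s)
        covered = set()
        for s in maximal:
            child = build(s, [x for x in available if x < s])
            connect(node, child)
            covered |= s
        for label in members - covered:
            connect(node, index[label])
        return node

    top = build(tree.leaves - {anchor}, sets)
    connect(top, index[anchor])
    # leaf node ids coincide with taxon row indices
    return adj, {i: i for i in range(len(taxa))}


# ---------------------------------------------------------------------------
# heuristic and exact parsimony search
# ---------------------------------------------------------------------------


@dataclass
class TreeSet:
    """Equally most-parsimonious trees found by a search."""

    trees: list
    score: int

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree set")
        leaf_sets = {t.leaves for t in self.trees}
        if len(leaf_sets) > 1:
            raise ValueError("trees do not share a leaf set")

    def __len__(self):
        return len(self.trees)


def _adjacency_to_tree(adj: dict, taxa: list) -> Tree:
    leaves = frozenset(taxa)
    n = len(taxa)
    splits = set()
    for u, vs in adj.items():
        for v in vs:
            if u < v and u >= n and v >= n:
                side = _leafset_under(adj, v, u, n)
                if 2 <= len(side) <= n - 2:
                    splits.add(_canonical(frozenset(taxa[i] for i in side), leaves))
    return Tree(leaves=leaves, splits=frozenset(splits))


def _leafset_under(adj, start, block, n):
    out, stack, seen = [], [start], {block, start}
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return out


def _edges(adj):
    return [(u, v) for u, vs in adj.items() for v in vs if u < v]


def _copy(adj):
    return {k: set(v) for k, v in adj.items()}


def _insert_leaf(adj, leaf, edge, new_internal):
    u, v = edge
    adj[u].discard(v)
    adj[v].discard(u)
    adj[new_internal] = {u, v, leaf}
    adj[u].add(new_internal)
    adj[v].add(new_internal)
    adj.setdefault(leaf, set()).add(new_internal)


def _nni_neighbors(adj, n):
    """Yield adjacency dicts one NNI away (internal edges only)."""
    for u, v in _edges(adj):
        if u < n or v < n:
            continue
        _a, b = sorted(adj[u] - {v})
        c, d = sorted(adj[v] - {u})
        for x, y in ((b, c), (b, d)):
            yield _nni_apply(adj, u, v, x, y)


def _nni_apply(adj, u, v, x, y):
    nb = _copy(adj)
    nb[u].discard(x)
    nb[x].discard(u)
    nb[v].discard(y)
    nb[y].discard(v)
    nb[u].add(y)
    nb[y].add(u)
    nb[v].add(x)
    nb[x].add(v)
    return nb


def _spr_neighbors(adj, n):
    """Yield adjacency dicts one SPR move away (binary trees)."""
    directed = [(u, v) for u, vs in adj.items() for v in vs]
    for u, v in directed:
        # prune the subtree hanging from v: detach edge (u,v), suppress
        # the now degree-2 node u, regraft v onto every surviving edge
        if u < n:
            continue
        rest = sorted(adj[u] - {v})
        if len(rest) != 2:
            continue
        a, b = rest
        pruned = _copy(adj)
        pruned[u] = set()
        pruned[a].discard(u)
        pruned[b].discard(u)
        pruned[a].add(b)
        pruned[b].add(a)
        pruned[v].discard(u)
        forbidden = set(_component(pruned, v))
        for x, y in _edges({k: s for k, s in pruned.items() if k != u}):
            if x in forbidden or y in forbidden:
                continue
            if {x, y} == {a, b}:
                continue  # regrafting on the suppressed edge restores the tree
            nb = _copy(pruned)
            nb[x].discard(y)
            nb[y].discard(x)
            nb[u] = {x, y, v}
            nb[v].add(u)
            nb[x].add(u)
            nb[y].add(u)
            yield nb


def _component(adj, start):
    seen, stack = {start}, [start]
    while stack:
        z = stack.pop()
        for w in adj[z]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def enumerate_topologies(taxa: list):
    """Yield every unrooted binary topology on ``taxa`` as a Tree.

    (2n-5)!! topologies: 105 for 6 taxa, 135,135 for 9.
    """
    taxa = list(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    def grow(adj, next_leaf, next_internal):
        if next_leaf == n:
            yield adj
            return
        for edge in _edges(adj):
            nb = _copy(adj)
            _insert_leaf(nb, next_leaf, edge, next_internal)
            yield from grow(nb, next_leaf + 1, next_internal + 1)

    base = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    for adj in grow(base, 3, n + 1):
        yield _adjacency_to_tree(adj, taxa)


def parsimony_search(
    binary,
    n_replicates: int = 500,
    seed: int = 0,
    exact: bool = False,
    use_spr: bool = True,
) -> TreeSet:
    """Search for most-parsimonious binary trees.

    ``n_replicates`` random stepwise-addition starts are each refined by
    NNI hill-climbing, falling back to SPR when NNI finds no improving
    move.  All distinct topologies attaining the best score are
    returned.  With ``exact=True`` every unrooted topology is scored
    instead (feasible for the study's ≤9 taxa).
    """
    df = _character_matrix(binary)
    taxa = sorted(df.index)
    n = len(taxa)
    if n < 4:
        raise ValueError("parsimony search needs at least 4 taxa")
    states, weights = _patterns(df, taxa)
    leaf_of = {i: i for i in range(n)}

    def score(adj):
        return _score_patterns(adj, leaf_of, states, weights)

    if exact:
        best_score, best = None, []
        for tree in enumerate_topologies(taxa):
            adj, _ = _tree_to_adjacency(tree, taxa)
            s = _score_patterns(adj, {i: i for i in range(n)}, states, weights)
            if best_score is None or s < best_score:
                best_score, best = s, [tree]
            elif s == best_score:
                best.append(tree)
        uniq = {t.splits: t for t in best}
        return TreeSet(trees=list(uniq.values()), score=int(best_score))

    rng = np.random.default_rng(seed)
    best_score = None
    best: dict = {}
    for _ in range(n_replicates):
        order = list(rng.permutation(n))
        adj = {order[0]: {n}, order[1]: {n}, order[2]: {n}, n: set(order[:3])}
        next_internal = n + 1
        for leaf in order[3:]:
            trials = []
            for edge in _edges(adj):
                nb = _copy(adj)
                _insert_leaf(nb, leaf, edge, next_internal)
                trials.append((score(nb), nb))
            smin = min(t[0] for t in trials)
            cands = [nb for s, nb in trials if s == smin]
            adj = cands[rng.integers(len(cands))]
            next_internal += 1
        cur = score(adj)
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbors(adj, n):
                s = score(nb)
                if s < cur:
                    adj, cur = nb, s
                    improved = True
                    break
            if not improved and use_spr:
                for nb in _spr_neighbors(adj, n):
                    s = score(nb)
                    if s < cur:
                        adj, cur = nb, s
                        improved = True
                        break
        tree = _adjacency_to_tree(adj, taxa)
        if best_score is None or cur < best_score:
            best_score, best = cur, {tree.splits: tree}
        elif cur == best_score:
            best.setdefault(tree.splits, tree)
    return TreeSet(trees=list(best.values()), score=int(best_score))


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def majority_rule_consensus(trees, cutoff: float = 0.5) -> Tree:
    """Strict majority-rule consensus: keep splits in > cutoff of trees.

    ``cutoff`` must be ≥ 0.5 so that retained splits are pairwise
    compatible; splits occurring in exactly half the trees are excluded
    (PAUP-compatible strict ">").  Accepts a TreeSet or a list of Trees.
    """
    tree_list = list(getattr(trees, "trees", trees))
    if not tree_list:
        raise ValueError("no trees to form a consensus of")
    if cutoff < 0.5:
        raise ValueError("cutoff below 0.5 can retain incompatible splits")
    leaves = tree_list[0].leaves
    if any(t.leaves != leaves for t in tree_list):
        raise ValueError("trees do not share a leaf set")
    counts: dict = {}
    for t in tree_list:
        for s in t.splits:
            counts[s] = counts.get(s, 0) + 1
    keep = frozenset(s for s, c in counts.items() if c > cutoff * len(tree_list))
    return Tree(leaves=leaves, splits=keep)
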