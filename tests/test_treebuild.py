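"""NJ, parsimony and consensus against exhaustive / closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cghphylo.io import Tree, read_newick
from cghphylo.treebuild import (
    enumerate_topologies,
    fitch_score,
    majority_rule_consensus,
    neighbor_joining,
    parsimony_search,
)
from conftest import random_binary_newick


def path_matrix(tree):
    taxa = sorted(tree.leaves)
    return pd.DataFrame(
        [[tree.path_length(a, b) for b in taxa] for a in taxa], index=taxa, columns=taxa
    )


class TestNeighborJoining:
    def test_additive_quartet_exact_topology_and_lengths(self):
        t = read_newick("((A:1,B:2):1,(C:3,D:1):0);")
        nj = neighbor_joining(path_matrix(t))
        assert nj.has_split({"A", "B"})
        for a, b in itertools.combinations("ABCD", 2):
            assert nj.path_length(a, b) == pytest.approx(t.path_length(a, b))
        assert nj.branch_lengths[frozenset({"C", "D"})] == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        nj = neighbor_joining(d)
        # three-point formulas: lA=(dAB+dAC-dBC)/2 etc.
        assert nj.branch_lengths["A"] == pytest.approx(1.0)
        assert nj.branch_lengths["B"] == pytest.approx(2.0)
        assert nj.branch_lengths["C"] == pytest.approx(3.0)

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_recovers_random_additive_matrices(self, rng, n_taxa):
        taxa = [f"t{i}" for i in range(n_taxa)]
        for _ in range(25):
            t = read_newick(random_binary_newick(taxa, rng, with_lengths=True))
            nj = neighbor_joining(path_matrix(t))
            assert nj.splits == t.splits

    def test_matches_scikit_bio_on_random_matrix(self, rng):
        """Independent NJ implementation agrees on topology."""
        skbio = pytest.importorskip("skbio")
        taxa = [f"t{i}" for i in range(6)]
        t = read_newick(random_binary_newick(taxa, rng, with_lengths=True))
        dm = path_matrix(t)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index)))
        ours = neighbor_joining(dm)
        theirs = read_newick(str(sk_tree).strip())
        assert ours.splits == theirs.splits

    def test_too_few_taxa(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"], columns=["A", "B"], dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(d)

    def test_no_negative_branch_lengths(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        t = read_newick(random_binary_newick(taxa, rng, with_lengths=True))
        d = path_matrix(t) + rng.uniform(0, 0.4, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d.values, 0.0)
        nj = neighbor_joining(d)
        assert all(v >= 0 for v in nj.branch_lengths.values())


def brute_force_parsimony(tree, chars):
    """Minimum changes over all internal labelings (exhaustive oracle)."""
    from cghphylo.treebuild import _tree_to_adjacency

    taxa = sorted(tree.leaves)
    adj, _ = _tree_to_adjacency(tree, taxa)
    internal = [v for v in adj if v >= len(taxa)]
    edges = [(u, v) for u, vs in adj.items() for v in vs if u < v]
    total = 0
    for _, col in chars.items():
        states = {i: col[t] for i, t in enumerate(taxa)}
        best = None
        leaf_opts = [
            [int(states[i])] if not np.isnan(states[i]) else [0, 1] for i in range(len(taxa))
        ]
        for leaf_assign in itertools.product(*leaf_opts):
            for assign in itertools.product([0, 1], repeat=len(internal)):
                lab = dict(zip(internal, assign))
                lab.update(dict(enumerate(leaf_assign)))
                changes = sum(lab[u] != lab[v] for u, v in edges)
                best = changes if best is None else min(best, changes)
        total += best
    return total


class TestFitchScore:
    @pytest.mark.parametrize(
        "pattern,expected",
        [({"A": 1, "B": 1, "C": 0, "D": 0}, 1), ({"A": 1, "C": 1, "B": 0, "D": 0}, 2),
         ({"A": 1, "B": 1, "C": 1, "D": 1}, 0)],
    )
    def test_hand_checked_quartet_patterns(self, quartet_tree, pattern, expected):
        chars = pd.DataFrame({"g": pattern}).astype(float)
        assert fitch_score(quartet_tree, chars) == expected

    def test_missing_is_wildcard(self, quartet_tree):
        chars = pd.DataFrame({"g": {"A": 1, "B": np.nan, "C": 0, "D": 0}}).astype(float)
        assert fitch_score(quartet_tree, chars) == 1

    def test_matches_exhaustive_labeling_oracle(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        for _ in range(5):
            tree = read_newick(random_binary_newick(taxa, rng))
            chars = pd.DataFrame(
                rng.integers(0, 2, size=(6, 8)).astype(float), index=taxa
            )
            chars.iloc[rng.random((6, 8)) < 0.15] = np.nan
            assert fitch_score(tree, chars) == brute_force_parsimony(tree, chars)

    def test_multifurcating_tree_scored_exactly(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        star = Tree(leaves=frozenset(taxa))
        chars = pd.DataFrame(rng.integers(0, 2, size=(5, 10)).astype(float), index=taxa)
        assert fitch_score(star, chars) == brute_force_parsimony(star, chars)

    def test_leaf_missing_from_matrix(self, quartet_tree):
        chars = pd.DataFrame({"g": {"A": 1, "B": 0, "C": 0}}).astype(float)
        with pytest.raises(ValueError, match="absent"):
            fitch_score(quartet_tree, chars)


class TestParsimonySearch:
    def test_105_topologies_for_six_taxa(self):
        assert sum(1 for _ in enumerate_topologies([f"t{i}" for i in range(6)])) == 105

    def test_heuristic_matches_exhaustive_on_six_taxa(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        for trial in range(3):
            chars = pd.DataFrame(rng.integers(0, 2, size=(6, 30)).astype(float), index=taxa)
            exact = parsimony_search(chars, exact=True)
            heur = parsimony_search(chars, n_replicates=10, seed=trial)
            assert heur.score == exact.score
            assert {t.splits for t in heur.trees} <= {t.splits for t in exact.trees}

    def test_generating_topology_found_from_clean_loss_signal(self, rng):
        """Characters = clades of a known tree are perfect synapomorphies."""
        nwk = "((A,B),((C,D),(E,F)));"
        tree = read_newick(nwk)
        taxa = sorted(tree.leaves)
        cols = {}
        i = 0
        for side in [{"A", "B"}, {"C", "D"}, {"E", "F"}, {"C", "D", "E", "F"}]:
            for _ in range(5):
                cols[f"g{i}"] = {t: 0.0 if t in side else 1.0 for t in taxa}
                i += 1
        chars = pd.DataFrame(cols)
        ts = parsimony_search(chars, n_replicates=20, seed=0)
        assert tree.splits in {t.splits for t in ts.trees}

    def test_more_replicates_never_worse(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        chars = pd.DataFrame(rng.integers(0, 2, size=(7, 40)).astype(float), index=taxa)
        s1 = parsimony_search(chars, n_replicates=1, seed=5).score
        s50 = parsimony_search(chars, n_replicates=50, seed=5).score
        assert s50 <= s1

    def test_deterministic_at_fixed_seed(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        chars = pd.DataFrame(rng.integers(0, 2, size=(6, 25)).astype(float), index=taxa)
        a = parsimony_search(chars, n_replicates=8, seed=42)
        b = parsimony_search(chars, n_replicates=8, seed=42)
        assert a.score == b.score
        assert {t.splits for t in a.trees} == {t.splits for t in b.trees}


class TestConsensus:
    def test_identical_inputs_return_same_tree(self):
        t = read_newick("((A,B),(C,(D,E)));")
        assert majority_rule_consensus([t, t, t]).splits == t.splits

    def test_two_thirds_majority_kept(self):
        t1 = read_newick("((A,B),(C,D),E);")
        t2 = read_newick("((A,B),(C,E),D);")
        cons = majority_rule_consensus([t1, t2, t1])
        assert cons.has_split({"A", "B"})
        assert cons.has_split({"C", "D"})
        assert not cons.has_split({"C", "E"})

    def test_exactly_half_excluded(self):
        t1 = read_newick("((A,B),(C,D));")
        t2 = read_newick("((A,C),(B,D));")
        assert majority_rule_consensus([t1, t2]).splits == frozenset()

    def test_consensus_splits_always_compatible(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        trees = [read_newick(random_binary_newick(taxa, rng)) for _ in range(9)]
        cons = majority_rule_consensus(trees)  # Tree.__post_init__ validates
        assert cons.leaves == frozenset(taxa)

    def test_low_cutoff_rejected(self):
        t = read_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            majority_rule_consensus([t], cutoff=0.3)
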