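"""Shared fixtures: small trees and simulated experiments.

Random trees for property tests are built here by plain random
pair-joining, independently of the package's tree machinery, so tests
that compare against them are genuine oracles.
"""

from __future__ import annotations

import numpy as np
import pytest

from cghphylo.io import read_newick
from cghphylo.simulate import SimConfig, simulate_divergence, simulate_slides


def random_binary_newick(taxa, rng, with_lengths=False, max_len=1.0):
    """Random unrooted binary tree by iterative pair joining."""
    nodes = [f"{t}" for t in taxa]
    if with_lengths:
        nodes = [f"{t}:{rng.uniform(0.05, max_len):.6f}" for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        length = f":{rng.uniform(0.05, max_len):.6f}" if with_lengths else ""
        nodes.append(f"({a},{b}){length}")
    return "(" + ",".join(nodes) + ");"


@pytest.fixture
def rng():
    return np.random.default_rng(20110487)


@pytest.fixture
def quartet_tree():
    return read_newick("((A,B),(C,D));")


@pytest.fixture
def small_experiment():
    """A clean 4-taxon experiment: low noise, some loss, with dye swaps."""
    tree = read_newick("((REF:0.02,B:0.03):0.01,(C:0.04,D:0.05):0.02);")
    cfg = SimConfig(
        n_genes=400,
        n_replicates=4,
        noise_sd=0.1,
        loss_rate=1.0,
        reference="REF",
        include_self_self=True,
        seed=7,
    )
    truth = simulate_divergence(tree, cfg)
    slides = simulate_slides(truth, cfg)
    return cfg, truth, slides
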