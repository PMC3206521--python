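"""Ground-truth generator: divergence, loss, slides, dye swaps."""

import numpy as np
import pandas as pd
import pytest

from cghphylo.io import read_newick
from cghphylo.simulate import (
    SimConfig,
    simulate_divergence,
    simulate_experiment,
    simulate_slides,
)

TREE = "((REF:0.02,B:0.03):0.01,(C:0.04,D:0.05):0.02);"


def make(config_kwargs=None, newick=TREE):
    kwargs = {"n_genes": 300, "reference": "REF", "seed": 1}
    kwargs.update(config_kwargs or {})
    cfg = SimConfig(**kwargs)
    tree = read_newick(newick)
    return tree, cfg


class TestDivergence:
    def test_zero_branch_lengths_mean_zero_divergence(self):
        tree, cfg = make(newick="((REF:0,B:0):0,(C:0,D:0):0);")
        truth = simulate_divergence(tree, cfg)
        assert (truth.divergence.to_numpy() == 0).all()
        assert (truth.presence.to_numpy() == 1).all()

    def test_no_loss_without_loss_rate(self):
        tree, cfg = make({"loss_rate": 0.0})
        truth = simulate_divergence(tree, cfg)
        assert (truth.presence.to_numpy() == 1).all()

    def test_reference_row_invariants(self):
        tree, cfg = make({"loss_rate": 3.0})
        truth = simulate_divergence(tree, cfg)
        assert (truth.divergence["REF"] == 0).all()
        assert (truth.presence["REF"] == 1).all()

    def test_mean_divergence_tracks_path_length(self):
        tree, cfg = make({"n_genes": 10_000})
        truth = simulate_divergence(tree, cfg)
        informative = truth.per_gene_rate > 0  # controls excluded
        for taxon in ("B", "C", "D"):
            path = tree.path_length("REF", taxon)
            ratio = truth.divergence.loc[informative, taxon].mean() / path
            assert ratio == pytest.approx(1.0, abs=0.05)

    def test_loss_fraction_matches_death_process(self):
        tree, cfg = make({"n_genes": 20_000, "loss_rate": 10.0})
        truth = simulate_divergence(tree, cfg)
        for taxon in ("B", "C", "D"):
            expected = np.exp(-cfg.loss_rate * tree.path_length("REF", taxon))
            observed = truth.presence[taxon].iloc[cfg.n_controls :].mean()
            assert observed == pytest.approx(expected, abs=0.02)

    def test_loss_is_irreversible_on_shared_branches(self):
        """A gene lost on the C+D stem must be absent in both C and D."""
        nwk = "((REF:0.01,B:0.01):0.01,(C:0.0,D:0.0):0.5);"
        tree, cfg = make({"n_genes": 5000, "loss_rate": 2.0}, newick=nwk)
        truth = simulate_divergence(tree, cfg)
        # pendant branches of C and D have length 0: every loss is shared
        pd.testing.assert_series_equal(
            truth.presence["C"], truth.presence["D"], check_names=False
        )

    def test_control_genes_silent_and_retained(self):
        tree, cfg = make({"loss_rate": 5.0})
        truth = simulate_divergence(tree, cfg)
        ctrl = list(truth.control_genes)
        assert len(ctrl) == cfg.n_controls
        assert (truth.divergence.loc[ctrl].to_numpy() == 0).all()
        assert (truth.presence.loc[ctrl].to_numpy() == 1).all()

    def test_reproducible_from_seed(self):
        tree, cfg = make({"loss_rate": 1.0})
        a = simulate_divergence(tree, cfg)
        b = simulate_divergence(tree, cfg)
        pd.testing.assert_frame_equal(a.divergence, b.divergence)
        pd.testing.assert_frame_equal(a.presence, b.presence)

    def test_unknown_reference_rejected(self):
        tree, _ = make()
        with pytest.raises(ValueError, match="reference"):
            simulate_divergence(tree, SimConfig(reference="NOPE"))


class TestSlides:
    def test_noise_free_ratio_is_linear_in_divergence(self):
        tree, cfg = make({"noise_sd": 0.0, "dye_swap": False})
        truth, slides = simulate_experiment(tree, cfg)
        slide = next(s for s in slides if s.taxon == "D")
        m = slide.oriented_log2_ratio()
        present = truth.presence["D"] == 1
        want = -cfg.slope * truth.divergence["D"]
        np.testing.assert_allclose(m[present.to_numpy()], want[present], atol=1e-9)

    def test_absent_genes_sit_at_background(self):
        tree, cfg = make({"noise_sd": 0.0, "dye_swap": False, "loss_rate": 5.0})
        truth, slides = simulate_experiment(tree, cfg)
        slide = next(s for s in slides if s.taxon == "D")
        absent = (truth.presence["D"] == 0).to_numpy()
        assert absent.any()
        np.testing.assert_allclose(
            slide.oriented_log2_ratio()[absent], cfg.absent_shift, atol=1e-9
        )

    def test_dye_swap_negates_raw_ratio(self):
        tree, cfg = make({"noise_sd": 0.0})
        truth, slides = simulate_experiment(tree, cfg)
        std = next(s for s in slides if s.taxon == "B" and not s.swapped)
        swp = next(s for s in slides if s.taxon == "B" and s.swapped)
        raw_std = np.log2(std.spots["ch1_signal"] / std.spots["ch2_signal"])
        raw_swp = np.log2(swp.spots["ch1_signal"] / swp.spots["ch2_signal"])
        np.testing.assert_allclose(raw_swp, -raw_std, atol=1e-9)
        np.testing.assert_allclose(
            swp.oriented_log2_ratio().to_numpy(), std.oriented_log2_ratio().to_numpy(), atol=1e-9
        )

    def test_self_self_slides_are_null(self):
        tree, cfg = make({"noise_sd": 0.0, "include_self_self": True, "dye_offset": 0.0})
        truth, slides = simulate_experiment(tree, cfg)
        self_self = [s for s in slides if s.taxon == "REF"]
        assert len(self_self) == cfg.n_replicates
        for s in self_self:
            np.testing.assert_allclose(s.oriented_log2_ratio().to_numpy(), 0.0, atol=1e-9)

    def test_balanced_dye_swap_cancels_constant_offset(self):
        tree, cfg = make({"noise_sd": 0.0, "dye_offset": 0.7})
        truth, slides = simulate_experiment(tree, cfg)
        pair = [s for s in slides if s.taxon == "C"][:2]
        oriented = np.vstack([s.oriented_log2_ratio().to_numpy() for s in pair])
        averaged = oriented.mean(axis=0)
        present = (truth.presence["C"] == 1).to_numpy()
        want = -cfg.slope * truth.divergence["C"].to_numpy()
        np.testing.assert_allclose(averaged[present], want[present], atol=1e-9)

    def test_flag_and_saturation_rates(self):
        tree, cfg = make({"n_genes": 5000, "flag_rate": 0.1, "saturation_rate": 0.05})
        truth, slides = simulate_experiment(tree, cfg)
        flags = np.concatenate([s.spots["flag"].to_numpy() for s in slides])
        sats = np.concatenate([s.spots["saturation_pct"].to_numpy() for s in slides])
        assert (flags < 0).mean() == pytest.approx(0.1, abs=0.01)
        assert (sats > 0).mean() == pytest.approx(0.05, abs=0.01)

    def test_replicate_count_and_orientation_scheme(self):
        tree, cfg = make({"n_replicates": 4})
        _, slides = simulate_experiment(tree, cfg)
        by_taxon = {}
        for s in slides:
            by_taxon.setdefault(s.taxon, []).append(s.swapped)
        for taxon, swaps in by_taxon.items():
            assert len(swaps) == 4
            assert sum(swaps) == 2  # balanced dye swaps

    def test_zero_noise_euclidean_monotone_in_path_length(self):
        """Caterpillar fixture: rows further down the tree drift further."""
        nwk = "((REF:0.01,B:0.01):0.01,(C:0.01,(D:0.01,E:0.02):0.01):0.01);"
        tree, cfg = make({"noise_sd": 0.0, "n_genes": 4000, "dye_swap": False}, newick=nwk)
        truth = simulate_divergence(tree, cfg)
        ideal = -cfg.slope * truth.divergence
        ref_dist = {
            t: float(np.linalg.norm(ideal[t])) for t in ("B", "C", "D", "E")
        }
        path = {t: tree.path_length("REF", t) for t in ref_dist}
        order_by_path = sorted(path, key=path.get)
        order_by_dist = sorted(ref_dist, key=ref_dist.get)
        assert order_by_path == order_by_dist
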