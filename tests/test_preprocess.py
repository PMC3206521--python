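"""Filtering and the four normalization routes."""

import numpy as np
import pandas as pd
import pytest

from cghphylo.io import RatioMatrix, SlideTable, read_newick
from cghphylo.preprocess import (
    FilterPolicy,
    filter_presence,
    filter_spots,
    normalize_linear,
    normalize_loess,
    normalize_spline,
)
from cghphylo.simulate import SimConfig, simulate_divergence, simulate_slides


def flat_tree():
    return read_newick("(REF:0.0,B:0.0,C:0.0);")


def clean_slides(**kw):
    """Slides with zero biological signal so residuals isolate artefacts."""
    defaults = dict(n_genes=2000, noise_sd=0.0, dye_swap=False, reference="REF", seed=3)
    defaults.update(kw)
    cfg = SimConfig(**defaults)
    truth = simulate_divergence(flat_tree(), cfg)
    return cfg, simulate_slides(truth, cfg)


class TestFilterSpots:
    def test_flagged_spot_masked(self, small_experiment):
        cfg, truth, slides = small_experiment
        slides[0].spots.loc[5, "flag"] = -100
        rm = filter_spots(slides, FilterPolicy(drop_flagged=True))
        assert np.isnan(rm.values.iloc[5, 0])

    def test_disabled_filters_keep_everything(self):
        cfg, slides = clean_slides(flag_rate=0.2, saturation_rate=0.1)
        policy = FilterPolicy(drop_flagged=False, max_saturation=100.0, min_roundness=0.0)
        rm = filter_spots(slides, policy)
        assert rm.values.notna().all().all()

    def test_masked_fraction_tracks_flag_rate(self):
        cfg, slides = clean_slides(n_genes=5000, flag_rate=0.1)
        rm = filter_spots(slides, FilterPolicy(drop_flagged=True))
        assert rm.values.isna().mean().mean() == pytest.approx(0.1, abs=0.01)

    def test_roundness_filter_works_when_enabled(self):
        cfg, slides = clean_slides()
        rm = filter_spots(slides, FilterPolicy(min_roundness=0.85))
        # simulator draws roundness uniform on [0.7, 1.0]: half the spots go
        assert rm.values.isna().mean().mean() == pytest.approx(0.5, abs=0.05)

    def test_mismatched_gene_universe_rejected(self):
        cfg, slides = clean_slides(n_genes=100)
        slides[1].spots.drop(index=[0], inplace=True)
        with pytest.raises(ValueError, match="universe"):
            filter_spots(slides)


class TestFilterPresence:
    def _rm(self, seen_per_gene, n_slides=10):
        values = pd.DataFrame(
            {f"s{i}": [0.0 if i < seen else np.nan for seen in seen_per_gene]
             for i in range(n_slides)},
            index=[f"g{j}" for j in range(len(seen_per_gene))],
        )
        return RatioMatrix(values=values, slide_taxa={f"s{i}": "X" for i in range(n_slides)})

    def test_forty_percent_rule_boundary(self):
        rm = self._rm([3, 4, 10])
        out = filter_presence(rm, 0.4)
        assert list(out.values.index) == ["g1", "g2"]  # 3/10 removed, 4/10 kept

    def test_zero_fraction_is_identity(self):
        rm = self._rm([0, 5])
        assert filter_presence(rm, 0.0) is rm

    def test_idempotent(self):
        rm = self._rm([2, 5, 7, 10])
        once = filter_presence(rm, 0.4)
        twice = filter_presence(once, 0.4)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestNormalizeLinear:
    def test_shifts_by_control_mean(self):
        values = pd.DataFrame({"s1": [0.3, 0.3, 1.0, -0.5]}, index=["ctrl_01", "ctrl_02", "g1", "g2"])
        rm = RatioMatrix(values=values, slide_taxa={"s1": "X"})
        out = normalize_linear(rm, ["ctrl_01", "ctrl_02"])
        np.testing.assert_allclose(out.values["s1"], [0.0, 0.0, 0.7, -0.8])

    def test_identity_when_controls_centred(self):
        values = pd.DataFrame({"s1": [0.2, -0.2, 1.0]}, index=["ctrl_01", "ctrl_02", "g1"])
        rm = RatioMatrix(values=values, slide_taxa={"s1": "X"})
        out = normalize_linear(rm, ["ctrl_01", "ctrl_02"])
        pd.testing.assert_frame_equal(out.values, rm.values)

    def test_recovers_simulated_dye_offset(self):
        cfg, slides = clean_slides(dye_offset=0.45)
        rm = filter_spots(slides)
        out = normalize_linear(rm, [f"ctrl_{i+1:02d}" for i in range(12)])
        np.testing.assert_allclose(out.values.to_numpy(), 0.0, atol=1e-9)

    def test_slide_without_controls_errors(self):
        values = pd.DataFrame({"s1": [np.nan, 1.0]}, index=["ctrl_01", "g1"])
        rm = RatioMatrix(values=values, slide_taxa={"s1": "X"})
        with pytest.raises(ValueError, match="s1"):
            normalize_linear(rm, ["ctrl_01"])


class TestNormalizeLoess:
    def test_constant_offset_removed(self):
        cfg, slides = clean_slides(dye_offset=0.5)
        rm = filter_spots(slides)
        out = normalize_loess(rm, slides, degree=2)
        assert out.values.abs().mean().mean() < 1e-6

    def test_intensity_dependent_bias_removed(self):
        cfg, slides = clean_slides(bias_amplitude=0.4, bias_coefs=(1.0, 0.0))
        rm = filter_spots(slides)
        out = normalize_loess(rm, slides, degree=2)
        assert out.values.abs().mean().mean() < 0.02

    def test_quadratic_bias_needs_degree_freedom(self):
        cfg, slides = clean_slides(bias_amplitude=0.15, bias_coefs=(1.0, 0.0, 0.0))
        rm = filter_spots(slides)
        out = normalize_loess(rm, slides, degree=2, span=0.3)
        assert out.values.abs().mean().mean() < 0.02

    def test_per_tip_removes_block_offsets(self):
        cfg, slides = clean_slides(n_blocks=4, tip_offsets=(0.5, -0.2, 0.1, -0.4))
        rm = filter_spots(slides)
        out = normalize_loess(rm, slides, per_tip=True, degree=1)
        block_means = out.values.iloc[:, 0].groupby(rm.gene_blocks.to_numpy()).mean()
        np.testing.assert_allclose(block_means, 0.0, atol=1e-6)

    def test_degree_one_matches_statsmodels_lowess(self):
        """Cross-check the local-linear path against statsmodels."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        a = rng.uniform(8, 14, 600)
        m = 0.3 * (a - a.mean()) + rng.normal(0, 0.05, 600)
        from cghphylo.preprocess import _local_polynomial_fit

        ours = _local_polynomial_fit(a, m, a, span=0.4, degree=1, iterations=1)
        theirs = sm.nonparametric.lowess(m, a, frac=0.4, it=0, return_sorted=False)
        assert np.median(np.abs(ours - theirs)) < 0.01

    def test_mask_untouched(self):
        cfg, slides = clean_slides(flag_rate=0.1)
        rm = filter_spots(slides)
        out = normalize_loess(rm, slides, degree=2)
        pd.testing.assert_frame_equal(out.values.isna(), rm.values.isna())


class TestNormalizeSpline:
    def test_constant_offset_removed(self):
        cfg, slides = clean_slides(dye_offset=0.5)
        rm = filter_spots(slides)
        out = normalize_spline(rm, slides)
        assert out.values.abs().mean().mean() < 1e-3

    def test_single_outlier_barely_moves_fit(self):
        cfg, slides = clean_slides(bias_amplitude=0.2, bias_coefs=(1.0, 0.0))
        rm = filter_spots(slides)
        clean = normalize_spline(rm, slides)
        spiked = rm.values.copy()
        spiked.iloc[100, 0] += 30.0
        rm2 = rm.copy_with(spiked)
        dirty = normalize_spline(rm2, slides)
        others = np.ones(len(spiked), dtype=bool)
        others[100] = False
        diff = (dirty.values.iloc[others, 0] - clean.values.iloc[others, 0]).abs().max()
        assert diff < 0.05  # robust fit shrugs off one 30-unit spike

    def test_block_offsets_shrunk_toward_zero(self):
        cfg, slides = clean_slides(n_blocks=4, tip_offsets=(0.5, -0.2, 0.1, -0.4))
        rm = filter_spots(slides)
        shrunk = normalize_spline(rm, slides)
        whole_only = RatioMatrix(
            values=rm.values, slide_taxa=rm.slide_taxa, gene_blocks=None
        )
        unshrunk = normalize_spline(whole_only, slides)
        blocks = rm.gene_blocks.to_numpy()
        for g in range(4):
            sel = blocks == g
            with_blocks = abs(shrunk.values.iloc[sel, 0].mean())
            without = abs(unshrunk.values.iloc[sel, 0].mean())
            assert with_blocks < without


def test_all_normalizations_identity_on_clean_null_data():
    """No bias, no noise, no divergence: nothing to correct."""
    cfg, slides = clean_slides()
    rm = filter_spots(slides)
    controls = [f"ctrl_{i+1:02d}" for i in range(12)]
    for out in (
        normalize_linear(rm, controls),
        normalize_loess(rm, slides, degree=1, per_tip=True),
        normalize_loess(rm, slides, degree=2),
        normalize_spline(rm, slides),
    ):
        np.testing.assert_allclose(out.values.to_numpy(), rm.values.to_numpy(), atol=1e-8)
        pd.testing.assert_frame_equal(out.values.isna(), rm.values.isna())
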