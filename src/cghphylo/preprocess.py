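"""Spot filtering and within-slide normalization.

Four normalization routes are offered, matching common two-color array
practice: a linear (ratio-of-means) correction anchored on control
spots, print-tip lowess (local linear regression of M on A), loess
(local quadratic regression), and a robust regression spline with the
per-block coefficients shrunk toward the whole-slide fit.  All four are
per-slide location corrections of M as a function of A (or a constant):
they never alter the missing-value mask, the gene universe, or any
cross-slide structure.

M is the oriented log2(test/reference) ratio per spot and
A = (log2 ch1 + log2 ch2)/2 the mean log intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RatioMatrix, SlideTable

log = logging.getLogger(__name__)

__all__ = [
    "FilterPolicy",
    "filter_spots",
    "filter_presence",
    "normalize_linear",
    "normalize_loess",
    "normalize_spline",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Spot-level quality filters applied before normalization.

    ``min_presence_fraction`` of 0.4 reproduces the "40% present" rule:
    a gene must carry an unmasked measurement in at least 40% of the
    slides to be kept at all.  The roundness cutoff is disabled by
    default (manufacturer-recommended value unpublished); the simulator
    emits a roundness column so the filter stays testable.
    """

    drop_flagged: bool = True
    max_saturation: float = 50.0
    min_roundness: float = 0.0
    min_presence_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.min_presence_fraction <= 1.0:
            raise ValueError("min_presence_fraction must lie in [0, 1]")
        if not 0.0 <= self.max_saturation <= 100.0:
            raise ValueError("max_saturation is a percentage")


def _slide_ids(slides) -> list:
    ids = []
    for i, s in enumerate(slides):
        sid = s.slide_id or f"slide{i + 1}"
        while sid in ids:
            sid += "b"
        ids.append(sid)
    return ids


def filter_spots(slides: list, policy: FilterPolicy = FilterPolicy()) -> RatioMatrix:
    """Oriented log-ratios with bad spots masked, one column per slide.

    Flagged, over-saturated and (optionally) low-roundness spots become
    NaN; nonpositive channel signals are always masked — no pseudocount
    is ever applied before the log transform.  A slide left with no
    usable spots is reported at warning level, never an error.
    """
    if not slides:
        raise ValueError("no slides")
    universe = list(slides[0].spots["gene_id"])
    for s in slides[1:]:
        if set(s.spots["gene_id"]) != set(universe):
            raise ValueError("slides do not share a gene universe")
    ids = _slide_ids(slides)
    cols = {}
    for sid, slide in zip(ids, slides):
        m = slide.oriented_log2_ratio().reindex(universe).to_numpy(float)
        sp = slide.spots.set_index("gene_id").reindex(universe)
        bad = np.zeros(len(universe), dtype=bool)
        if policy.drop_flagged:
            bad |= sp["flag"].to_numpy(float) < 0
        bad |= sp["saturation_pct"].to_numpy(float) > policy.max_saturation
        if policy.min_roundness > 0:
            bad |= sp["roundness"].to_numpy(float) < policy.min_roundness
        m[bad] = np.nan
        if np.all(np.isnan(m)):
            log.warning("slide %s has no usable spots after filtering", sid)
        cols[sid] = m
    values = pd.DataFrame(cols, index=pd.Index(universe, name="gene_id"))
    blocks = slides[0].spots.set_index("gene_id")["block_id"].reindex(universe)
    rm = RatioMatrix(
        values=values,
        slide_taxa={sid: s.taxon for sid, s in zip(ids, slides)},
        gene_blocks=blocks,
        provenance=(f"filter_spots({policy})",),
    )
    if policy.min_presence_fraction > 0:
        rm = filter_presence(rm, policy.min_presence_fraction)
    return rm


def filter_presence(ratios: RatioMatrix, min_fraction: float) -> RatioMatrix:
    """Drop genes observed in fewer than ``min_fraction`` of the slides.

    The boundary is inclusive: with 10 slides and ``min_fraction=0.4`` a
    gene seen in exactly 4 slides is retained.  Idempotent.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    if min_fraction == 0:
        return ratios
    n = ratios.values.shape[1]
    seen = ratios.values.notna().sum(axis=1)
    keep = seen >= min_fraction * n
    return ratios.copy_with(ratios.values.loc[keep], step=f"filter_presence({min_fraction})")


def normalize_linear(ratios: RatioMatrix, control_gene_ids) -> RatioMatrix:
    """Ratio-of-means linear normalization anchored on control spots.

    Per slide, the mean log-ratio of the control genes is subtracted
    from every entry, so controls average exactly zero afterwards.
    """
    controls = [g for g in control_gene_ids if g in ratios.values.index]
    if not controls:
        raise ValueError("no control genes present in the ratio matrix")
    out = ratios.values.copy()
    for sid in out.columns:
        ctrl = out.loc[controls, sid].dropna()
        if ctrl.empty:
            raise ValueError(f"slide {sid} has no unmasked control spot")
        out[sid] = out[sid] - ctrl.mean()
    return ratios.copy_with(out, step="normalize_linear")


# ---------------------------------------------------------------------------
# local polynomial (lowess / loess) smoothing
# ---------------------------------------------------------------------------


def _local_polynomial_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_out: np.ndarray,
    span: float = 0.4,
    degree: int = 1,
    iterations: int = 3,
) -> np.ndarray:
    """Tricube-weighted local polynomial regression, evaluated at x_out.

    degree 1 reproduces classical lowess; degree 2 is loess.  Robustness
    iterations downweight outliers with Tukey bisquare weights.  The
    smooth is computed on a quantile grid and linearly interpolated.
    """
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = len(xs)
    if n <= degree + 1:
        return np.full_like(x_out, ys.mean() if n else 0.0, dtype=float)
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    n_grid = min(80, n)
    grid = np.quantile(xs, np.linspace(0.0, 1.0, n_grid))
    robust = np.ones(n)

    fit_grid = np.zeros(n_grid)
    for _ in range(max(iterations, 1)):
        for gi, x0 in enumerate(grid):
            d = np.abs(xs - x0)
            # k-nearest-neighbour bandwidth
            h = np.partition(d, k - 1)[k - 1]
            if h == 0:
                h = max(d.max(), 1e-12)
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3 * robust
            sel = w > 0
            if sel.sum() <= degree:
                fit_grid[gi] = np.average(ys, weights=np.maximum(w, 1e-12))
                continue
            coefs = np.polyfit(xs[sel] - x0, ys[sel], degree, w=np.sqrt(w[sel]))
            fit_grid[gi] = coefs[-1]
        resid = ys - np.interp(xs, grid, fit_grid)
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        robust = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return np.interp(x_out, grid, fit_grid)


def _slide_intensities(slides: list, universe) -> dict:
    amap = {}
    for i, s in enumerate(slides):
        sid = s.slide_id or f"slide{i + 1}"
        amap[sid] = s.mean_log2_intensity().reindex(universe).to_numpy(float)
    return amap


def _correct_by_groups(m, a, groups, fit_one, min_spots, label):
    """Subtract a per-group M~A fit, falling back to one whole-slide fit."""
    out = m.copy()
    ok = ~np.isnan(m) & ~np.isnan(a)
    whole = None
    for g in np.unique(groups[ok]) if groups is not None else [None]:
        sel = ok if g is None else ok & (groups == g)
        if g is not None and sel.sum() < min_spots:
            if whole is None:
                whole = fit_one(a[ok], m[ok], a)
            log.info("%s: block %s too small (%d spots); whole-slide fit", label, g, sel.sum())
            out[sel] = m[sel] - whole[sel]
            continue
        fitted = fit_one(a[sel], m[sel], a)
        out[sel] = m[sel] - fitted[sel]
    return out


def normalize_loess(
    ratios: RatioMatrix,
    slides: list,
    per_tip: bool = False,
    degree: int = 2,
    span: float = 0.4,
    iterations: int = 3,
) -> RatioMatrix:
    """Local-regression normalization of M on A, per slide.

    ``degree=1`` with ``per_tip=True`` is print-tip lowess; ``degree=2``
    whole-slide is loess.  Blocks with too few spots fall back to the
    whole-slide fit (logged).
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 (lowess) or 2 (loess)")
    universe = ratios.values.index
    amap = _slide_intensities(slides, universe)
    groups = None
    if per_tip:
        if ratios.gene_blocks is None:
            raise ValueError("per-tip normalization needs print-tip blocks")
        groups = ratios.gene_blocks.to_numpy()
    min_spots = max(10 * (degree + 1), 20)

    def fit_one(ax, mx, a_all):
        return _local_polynomial_fit(ax, mx, a_all, span=span, degree=degree, iterations=iterations)

    out = ratios.values.copy()
    for sid in out.columns:
        if sid not in amap:
            raise ValueError(f"no slide table provides intensities for {sid}")
        m = out[sid].to_numpy(float)
        out[sid] = _correct_by_groups(m, amap[sid], groups, fit_one, min_spots, sid)
    name = "lowess" if degree == 1 else "loess"
    return ratios.copy_with(out, step=f"normalize_{name}(per_tip={per_tip}, span={span})")


# ---------------------------------------------------------------------------
# robust spline
# ---------------------------------------------------------------------------


def _bspline_basis(a: np.ndarray, knots_a: np.ndarray, df: int) -> np.ndarray:
    from scipy.interpolate import BSpline

    degree = 3
    n_inner = max(df - degree - 1, 0)
    lo, hi = knots_a.min(), knots_a.max()
    if hi <= lo:
        hi = lo + 1.0
    inner = np.quantile(knots_a, np.linspace(0, 1, n_inner + 2)[1:-1]) if n_inner else np.array([])
    t = np.r_[[lo] * (degree + 1), inner, [hi] * (degree + 1)]
    ac = np.clip(a, lo, hi)
    return BSpline.design_matrix(ac, t, degree).toarray()


def _irls_fit(X: np.ndarray, y: np.ndarray, iterations: int = 4) -> np.ndarray:
    w = np.ones(len(y))
    beta = None
    for _ in range(iterations):
        Xw = X * w[:, None]
        beta, *_ = np.linalg.lstsq(Xw.T @ X + 1e-8 * np.eye(X.shape[1]), Xw.T @ y, rcond=None)
        resid = y - X @ beta
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        w = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return beta


def normalize_spline(
    ratios: RatioMatrix,
    slides: list,
    df: int = 5,
    shrink_weight: float = 20.0,
) -> RatioMatrix:
    """Robust regression-spline normalization with block shrinkage.

    Per slide, a cubic B-spline of M on A (``df`` degrees of freedom) is
    fitted robustly (iterated Tukey-bisquare reweighting) for the whole
    slide and per print-tip block; block coefficients are shrunk toward
    the slide fit by a precision-weighted average with prior weight
    ``shrink_weight`` (an empirical-Bayes style compromise), and the
    shrunk fit is subtracted.  Without block information the whole-slide
    robust spline is used alone.
    """
    universe = ratios.values.index
    amap = _slide_intensities(slides, universe)
    groups = ratios.gene_blocks.to_numpy() if ratios.gene_blocks is not None else None
    out = ratios.values.copy()
    for sid in out.columns:
        if sid not in amap:
            raise ValueError(f"no slide table provides intensities for {sid}")
        m = out[sid].to_numpy(float)
        a = amap[sid]
        ok = ~np.isnan(m) & ~np.isnan(a)
        if ok.sum() <= df + 1:
            log.warning("slide %s: too few spots for spline fit; left unchanged", sid)
            continue
        X = _bspline_basis(a, a[ok], df)
        beta_slide = _irls_fit(X[ok], m[ok])
        corrected = m.copy()
        if groups is None:
            corrected[ok] = m[ok] - X[ok] @ beta_slide
        else:
            for g in np.unique(groups[ok]):
                sel = ok & (groups == g)
                nb = sel.sum()
                if nb <= df + 1:
                    beta = beta_slide
                else:
                    beta_block = _irls_fit(X[sel], m[sel])
                    beta = (nb * beta_block + shrink_weight * beta_slide) / (nb + shrink_weight)
                corrected[sel] = m[sel] - X[sel] @ beta
        out[sid] = corrected
    return ratios.copy_with(out, step=f"normalize_spline(df={df})")
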