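"""Presence/absence (genomotyping) calls from continuous hybridization values.

Three routes:

* GACK-style dynamic cutoff: per taxon, the distribution of the
  "present" component is estimated by locating the mode of the value
  distribution (present genes cluster near zero log-ratio) and
  mirroring its high side, giving a probability-of-presence for every
  value; an EPP threshold of e.g. 50% calls conserved (1) every gene
  with a 50%-or-greater chance of being present, inclusive at the
  boundary.
* Quartile binning of Bayesian level estimates: values pooled over the
  whole taxon-by-gene matrix, presence scored for values at or above
  the 75th (Q4), 50th (Q4-Q3) or 25th (Q4-Q2) percentile.
* MPP-style: transform (log passthrough or inverse hyperbolic sine),
  then either the EPP machinery on histogram-binned densities
  (binwidth 0.05 "norm" or Freedman-Diaconis "exp") or BPP, a
  two-component Gaussian mixture fitted by EM whose posterior
  probability of the high (present) component is thresholded at 0.5.

All calls carry enough provenance to be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .estimate import TaxonGeneMatrix

__all__ = [
    "BinaryMatrix",
    "PresenceModel",
    "fit_gack",
    "gack_binarize",
    "quartile_binarize",
    "mpp_binarize",
]

_ALLOWED = {0.0, 1.0}


@dataclass
class BinaryMatrix:
    """Taxa x genes calls: 1 present/conserved, 0 absent/diverged, NaN missing."""

    calls: pd.DataFrame
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = self.calls.to_numpy(float)
        bad = ~(np.isnan(arr) | np.isin(arr, list(_ALLOWED)))
        if bad.any():
            raise ValueError("binary matrix entries must be 0, 1 or missing")

    @property
    def taxa(self):
        return list(self.calls.index)


@dataclass
class PresenceModel:
    """Probability-of-presence as a function of the hybridization value.

    Estimated from one taxon's value distribution: the present
    component's density is the total density mirrored around the mode
    (values at or above the mode are assumed fully present), and
    P(present | v) = min(1, present density / total density),
    monotonized to be nondecreasing in v.
    """

    grid: np.ndarray
    prob: np.ndarray
    mode: float

    def __post_init__(self):
        if np.any(np.diff(self.prob) < -1e-9):
            raise ValueError("probability of presence must be nondecreasing in value")

    def probability_of_presence(self, values) -> np.ndarray:
        v = np.asarray(values, float)
        return np.interp(v, self.grid, self.prob, left=self.prob[0], right=self.prob[-1])

    def cutoff(self, epp: float) -> float:
        """Smallest grid value whose presence probability reaches epp%."""
        target = epp / 100.0
        idx = np.searchsorted(self.prob, target, side="left")
        if idx >= len(self.grid):
            return self.grid[-1]
        return float(self.grid[idx])


def fit_gack(values, min_values: int = 100, grid_size: int = 512) -> PresenceModel:
    """Mirrored-mode estimate of the present component for one taxon.

    Requires at least ``min_values`` unmasked values (pool taxa
    otherwise).  Degenerate all-identical input yields probability 1
    everywhere (no divergent tail to separate).
    """
    v = np.asarray(pd.Series(values).dropna(), float)
    if len(v) < min_values:
        raise ValueError(
            f"only {len(v)} values (< {min_values}); pool taxa or lower the floor"
        )
    if np.ptp(v) == 0:
        grid = np.array([v[0] - 1, v[0], v[0] + 1])
        return PresenceModel(grid=grid, prob=np.ones(3), mode=float(v[0]))
    kde = gaussian_kde(v)
    lo, hi = v.min(), v.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    mode = float(grid[np.argmax(dens)])
    mirrored = kde(2 * mode - grid)
    present = np.where(grid >= mode, dens, mirrored)
    with np.errstate(divide="ignore", invalid="ignore"):
        prob = np.where(dens > 0, np.minimum(1.0, present / dens), 1.0)
    prob[grid >= mode] = 1.0
    # monotonize: P(present) may not rise as the value falls
    prob = np.minimum.accumulate(prob[::-1])[::-1]
    return PresenceModel(grid=grid, prob=prob, mode=mode)


def gack_binarize(matrix: TaxonGeneMatrix, epp: float = 50.0, min_values: int = 100) -> BinaryMatrix:
    """EPP thresholding per taxon: 1 iff P(present) >= epp/100.

    ``epp`` is a percentage in [0, 100]; the boundary is inclusive
    ("50% or greater chance of being present" is conserved).  The
    presence model is fitted per taxon.
    """
    if not 0.0 <= epp <= 100.0:
        raise ValueError("epp is a percentage in [0, 100]")
    out = {}
    for taxon, row in matrix.values.iterrows():
        model = fit_gack(row, min_values=min_values)
        p = model.probability_of_presence(row.to_numpy(float))
        calls = np.where(np.isnan(row.to_numpy(float)), np.nan, (p >= epp / 100.0).astype(float))
        out[taxon] = calls
    calls = pd.DataFrame(out, index=matrix.values.columns).T
    return BinaryMatrix(calls=calls, method="gack", params={"epp": epp, "per_taxon": True})


_QUARTILE_PCT = {"Q4": 75.0, "Q3": 50.0, "Q2": 25.0}


def quartile_binarize(matrix: TaxonGeneMatrix, present_from: str = "Q4") -> BinaryMatrix:
    """Pooled quartile binning of (Bayesian) level estimates.

    All values are pooled to set the quartile boundaries; presence (1)
    is scored for values at or above the boundary implied by
    ``present_from`` (Q4: top quartile; Q3: top half; Q2: top three
    quarters), the lower quartiles — the smaller or negative
    hybridization ratios — scoring absent (0).  Ties at the boundary
    are present.
    """
    if present_from not in _QUARTILE_PCT:
        raise ValueError("present_from must be one of Q4, Q3, Q2")
    arr = matrix.values.to_numpy(float)
    pooled = arr[~np.isnan(arr)]
    if pooled.size == 0:
        raise ValueError("empty matrix")
    boundary = np.percentile(pooled, _QUARTILE_PCT[present_from])
    calls = np.where(np.isnan(arr), np.nan, (arr >= boundary).astype(float))
    return BinaryMatrix(
        calls=pd.DataFrame(calls, index=matrix.values.index, columns=matrix.values.columns),
        method="quartile",
        params={"present_from": present_from, "boundary": float(boundary)},
    )


def _freedman_diaconis_width(v: np.ndarray) -> float:
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    if iqr <= 0:
        iqr = np.ptp(v) or 1.0
    return 2.0 * iqr / np.cbrt(len(v))


def _binned_presence_probability(v: np.ndarray, width: float):
    """EPP machinery on histogram-binned densities (per taxon)."""
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.ones_like(v)
    edges = np.arange(lo, hi + width, width)
    if len(edges) < 4:
        edges = np.linspace(lo, hi, 4)
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = counts.astype(float)
    mode = centers[np.argmax(dens)]
    mirrored = np.interp(2 * mode - centers, centers, dens, left=0.0, right=0.0)
    present = np.where(centers >= mode, dens, mirrored)
    with np.errstate(divide="ignore", invalid="ignore"):
        prob = np.where(dens > 0, np.minimum(1.0, present / dens), 1.0)
    prob[centers >= mode] = 1.0
    prob = np.minimum.accumulate(prob[::-1])[::-1]
    return np.interp(v, centers, prob, left=prob[0], right=prob[-1])


def mpp_binarize(
    matrix: TaxonGeneMatrix,
    transform: str = "arsinh",
    method: str = "BPP",
    binwidth: str = "norm",
    epp: float = 50.0,
    seed: int = 0,
    input_scale: str = "log2",
) -> BinaryMatrix:
    """MPP-style transform + EPP/BPP presence calling, per taxon.

    ``transform='arsinh'`` maps linear-scale ratios through
    arsinh(x) = ln(x + sqrt(x^2 + 1)); with log2 input the values are
    first unlogged.  ``transform='log'`` keeps log-scale values
    (nonpositive linear inputs would be masked).  EPP uses histogram
    densities with binwidth 0.05 (``norm``) or the Freedman-Diaconis
    rule (``exp``); BPP fits a two-component Gaussian mixture by EM and
    calls present iff the posterior of the higher-mean component is at
    least 0.5 (ties present, consistent with the EPP rule).
    """
    if transform not in ("log", "arsinh"):
        raise ValueError("transform must be 'log' or 'arsinh'")
    if method not in ("EPP", "BPP"):
        raise ValueError("method must be 'EPP' or 'BPP'")
    if binwidth not in ("norm", "exp"):
        raise ValueError("binwidth must be 'norm' or 'exp'")
    arr = matrix.values.to_numpy(float)
    if input_scale == "log2":
        linear = np.exp2(arr)
    elif input_scale == "linear":
        linear = arr
    else:
        raise ValueError("input_scale must be 'log2' or 'linear'")

    if transform == "arsinh":
        tr = np.arcsinh(linear)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            tr = np.where(linear > 0, np.log(np.where(linear > 0, linear, 1.0)), np.nan)
        n_masked = int(np.isnan(tr).sum() - np.isnan(arr).sum())
        if n_masked > 0:
            import logging

            logging.getLogger(__name__).info(
                "log transform masked %d nonpositive values", n_masked
            )

    out = np.full_like(tr, np.nan)
    for i in range(tr.shape[0]):
        row = tr[i]
        ok = ~np.isnan(row)
        v = row[ok]
        if v.size < 4:
            continue
        if method == "EPP":
            width = 0.05 if binwidth == "norm" else _freedman_diaconis_width(v)
            prob = _binned_presence_probability(v, width)
            calls = (prob >= epp / 100.0).astype(float)
        else:
            calls = _bpp_calls(v, seed=seed)
        row_out = np.full_like(row, np.nan)
        row_out[ok] = calls
        out[i] = row_out
    return BinaryMatrix(
        calls=pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        method="mpp",
        params={
            "transform": transform,
            "method": method,
            "binwidth": binwidth,
            "epp": epp,
            "seed": seed,
        },
    )


def _bpp_calls(v: np.ndarray, seed: int = 0) -> np.ndarray:
    """Two-component Gaussian mixture posterior presence calls."""
    from sklearn.mixture import GaussianMixture

    if np.ptp(v) == 0:
        return np.ones_like(v)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        random_state=int(seed) % (2**32),
        n_init=3,
        means_init=np.array([[np.percentile(v, 10)], [np.percentile(v, 90)]]),
    )
    gm.fit(v[:, None])
    present = int(np.argmax(gm.means_.ravel()))
    post = gm.predict_proba(v[:, None])[:, present]
    return (post >= 0.5).astype(float)
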