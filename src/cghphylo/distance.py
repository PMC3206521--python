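"""Taxon x taxon distances from continuous values or presence calls.

Continuous routes are the classical ones: Euclidean distance over the
genes shared by each pair (rescaled for differing missingness) and the
correlation distance 1 - Pearson r.

The binary route is a death-process gene-content distance built for the
single-reference CGH design: every gene is present in the reference by
array design, and loss along branches is irreversible.  Under that
model, with p_i the fraction of genes called present in taxon i and
p_ij the fraction present in both i and j,

    E[p_i]  = exp(-d_i),    E[p_ij] = exp(-(d_i + d_j - shared_ij)),

where d_i is the loss-length of the path reference -> i and shared_ij
the loss-length shared by the two paths.  The moment estimator

    d(i, j) = ln( p_i * p_j / p_ij^2 )

therefore recovers the path length between i and j (the shared-branch
contribution cancels), and the reference is placed by extrapolation,
d(i, ref) = -ln p_i, without any self-self hybridization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import BinaryMatrix
from .estimate import TaxonGeneMatrix

log = logging.getLogger(__name__)

__all__ = ["DistanceMatrix", "euclidean_dist", "correlation_dist", "cgh_death_dist"]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative taxon x taxon distances with provenance."""

    matrix: pd.DataFrame
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = self.matrix.to_numpy(float)
        if list(self.matrix.index) != list(self.matrix.columns):
            raise ValueError("rows and columns must list the same taxa")
        if not np.allclose(arr, arr.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0):
            raise ValueError("self-distances must be zero")
        if not np.isfinite(arr).all():
            raise ValueError("distances must be finite")
        if (arr < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def taxa(self):
        return list(self.matrix.index)


def _pairs(values: pd.DataFrame):
    taxa = list(values.index)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            yield a, b


def euclidean_dist(matrix: TaxonGeneMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distance over the genes unmasked in both taxa.

    Each pair's squared distance is rescaled by G / G_shared (G the full
    gene count) so pairs with different missingness stay comparable.
    """
    values = matrix.values
    if values.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    G = values.shape[1]
    taxa = list(values.index)
    out = pd.DataFrame(0.0, index=taxa, columns=taxa)
    arr = values.to_numpy(float)
    for a, b in _pairs(values):
        x, y = arr[taxa.index(a)], arr[taxa.index(b)]
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 2:
            raise ValueError(f"taxa {a} and {b} share fewer than 2 genes")
        d2 = ((x[ok] - y[ok]) ** 2).sum() * (G / ok.sum())
        out.loc[a, b] = out.loc[b, a] = np.sqrt(d2)
    return DistanceMatrix(out, method="euclidean", params={"n_genes": G})


def correlation_dist(matrix: TaxonGeneMatrix) -> DistanceMatrix:
    """1 - Pearson correlation over shared unmasked genes, per pair."""
    values = matrix.values
    if values.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    taxa = list(values.index)
    out = pd.DataFrame(0.0, index=taxa, columns=taxa)
    arr = values.to_numpy(float)
    for a, b in _pairs(values):
        x, y = arr[taxa.index(a)], arr[taxa.index(b)]
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3:
            raise ValueError(f"taxa {a} and {b} share fewer than 3 genes")
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            raise ValueError(f"zero variance in the shared genes of {a} or {b}")
        r = np.corrcoef(xs, ys)[0, 1]
        out.loc[a, b] = out.loc[b, a] = max(0.0, 1.0 - r)
    return DistanceMatrix(out, method="correlation", params={})


def cgh_death_dist(
    binary: BinaryMatrix,
    include_reference: bool = False,
    reference: str | None = None,
    pseudocount: float = 0.5,
) -> DistanceMatrix:
    """Death-process gene-content distance from presence/absence calls.

    d(i, j) = ln(p_i p_j / p_ij^2) with presence fractions computed over
    the genes called in both members of the pair; a pseudocount (default
    0.5) is added to present and joint-present counts to avoid log(0).
    With ``include_reference`` the reference row is extrapolated as
    d(i, ref) = -ln p_i — all genes are present in the reference by
    array design, so no reference hybridization enters.  Negative
    estimates are clamped to 0 with a logged warning.
    """
    calls = binary.calls
    taxa = [t for t in calls.index if t != reference]
    if include_reference and reference is None:
        raise ValueError("include_reference requires naming the reference taxon")
    all_taxa = taxa + ([reference] if include_reference else [])
    out = pd.DataFrame(0.0, index=all_taxa, columns=all_taxa)
    arr = calls.loc[taxa].to_numpy(float)

    def presence_fraction(x, ok):
        return (np.nansum(x[ok]) + pseudocount) / (ok.sum() + pseudocount)

    for i, a in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            b = taxa[j]
            x, y = arr[i], arr[j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            n = ok.sum()
            if n == 0:
                raise ValueError(f"no shared calls between {a} and {b}")
            pi = presence_fraction(x, ok)
            pj = presence_fraction(y, ok)
            joint = (np.nansum(x[ok] * y[ok]) + pseudocount) / (n + pseudocount)
            if joint <= 0:
                raise ValueError(f"joint presence vanishes for {a}, {b}: data uninformative")
            d = np.log(pi * pj / joint**2)
            if d < 0:
                log.warning("negative death-process distance %.3g for (%s, %s); clamped", d, a, b)
                d = 0.0
            out.loc[a, b] = out.loc[b, a] = d
    if include_reference:
        for i, a in enumerate(taxa):
            x = arr[i]
            ok = ~np.isnan(x)
            if ok.sum() == 0:
                raise ValueError(f"no calls for {a}")
            d = -np.log(presence_fraction(x, ok))
            if d < 0:
                log.warning("negative extrapolated distance for (%s, reference); clamped", a)
                d = 0.0
            out.loc[a, reference] = out.loc[reference, a] = d
    return DistanceMatrix(
        out,
        method="cghdist",
        params={"pseudocount": pseudocount, "include_reference": include_reference},
    )
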