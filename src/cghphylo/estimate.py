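"""Collapse slide-level ratios to one hybridization value per taxon.

Two routes: a plain per-taxon mean or median of the replicate slides,
and a Bayesian relative hybridization level in the BAGEL tradition.
The Bayesian route fits, per gene, the linear model

    observed log-ratio on a slide of taxon s  =  mu_s - mu_ref + eps,
    eps ~ Normal(0, sigma^2),

under a flat prior, and reports the posterior means of all mu_s under
the sum-to-zero identifiability constraint — including an extrapolated
value for the reference taxon itself, which is what makes this route
insensitive to whether self-self reference slides are included: every
test-taxon hybridization informs mu_ref through the contrasts, whereas
the plain summaries can place the reference only from self-self slides.
Under a flat prior the posterior mean coincides with the least-squares
solution, so the estimates are closed form.

Only log-scale input is accepted (the model is additive in log space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RatioMatrix

__all__ = ["TaxonGeneMatrix", "BagelEstimate", "summarize_by_taxon", "bagel_estimate", "bagel_to_matrix"]


@dataclass
class TaxonGeneMatrix:
    """Taxa x genes continuous hybridization values.

    ``provenance`` is one of ``mean``/``median``/``bayes``; when
    ``bayes`` and the reference is included, the reference row is the
    model's extrapolated value, never a self-self summary.
    """

    values: pd.DataFrame
    provenance: str
    reference: str | None = None
    reference_included: bool = False

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate taxa")
        if self.reference_included and self.reference not in self.values.index:
            raise ValueError("reference marked included but missing from rows")

    @property
    def taxa(self):
        return list(self.values.index)

    @property
    def genes(self):
        return self.values.columns


@dataclass
class BagelEstimate:
    """Per-gene relative hybridization levels with uncertainties.

    ``levels``: gene x taxon posterior means mu_s (sum-to-zero per
    gene); ``level_sd``: matching standard errors; ``sigma``: per-gene
    residual sd.  Genes with observations from fewer than two taxa are
    absent from all three.
    """

    levels: pd.DataFrame
    level_sd: pd.DataFrame
    sigma: pd.Series
    reference: str

    def __post_init__(self):
        if (self.level_sd.to_numpy(float) <= 0).any():
            raise ValueError("uncertainties must be positive")


def summarize_by_taxon(ratios: RatioMatrix, stat: str = "mean") -> TaxonGeneMatrix:
    """Per-gene mean or median of each taxon's replicate slides.

    The reference row appears only if self-self slides are present; a
    taxon with no unmasked observation for a gene gets a missing entry.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    taxa = ratios.taxa()
    rows = {}
    for taxon in taxa:
        cols = [s for s in ratios.values.columns if ratios.slide_taxa[s] == taxon]
        sub = ratios.values[cols]
        rows[taxon] = sub.mean(axis=1) if stat == "mean" else sub.median(axis=1)
    values = pd.DataFrame(rows).T
    values.index.name = "taxon"
    return TaxonGeneMatrix(values=values, provenance=stat)


def bagel_estimate(
    ratios: RatioMatrix,
    reference: str,
    max_missing_taxa: float = 0.5,
    assume_log: bool = True,
) -> BagelEstimate:
    """Closed-form posterior means of per-taxon hybridization levels.

    Per gene, each unmasked slide of test taxon s contributes one
    observation of mu_s - mu_ref; self-self slides (taxon == reference)
    contribute observations of 0 and only inform sigma.  The flat-prior
    posterior mean is the least-squares fit with the sum-to-zero
    constraint over the taxa observed for that gene (reference always
    counted as observed: the array is designed on it).  Genes observed
    in fewer than 2 taxa, or missing more than ``max_missing_taxa`` of
    the test taxa, are dropped.
    """
    if not assume_log:
        raise ValueError("the Bayesian stage only accepts log-transformed data")
    slide_cols = list(ratios.values.columns)
    slide_tax = np.array([ratios.slide_taxa[s] for s in slide_cols])
    test_taxa = [t for t in ratios.taxa() if t != reference]
    all_taxa = [reference] + test_taxa
    vals = ratios.values.to_numpy(float)  # genes x slides

    levels, sds, sig, kept = [], [], [], []
    n_test = len(test_taxa)
    for gi, gene in enumerate(ratios.values.index):
        y = vals[gi]
        obs_taxa = []
        diffs = {}
        resid_ss, resid_n = 0.0, 0
        for t in test_taxa:
            sel = (slide_tax == t) & ~np.isnan(y)
            if sel.sum() == 0:
                continue
            obs_taxa.append(t)
            m = y[sel].mean()
            diffs[t] = m
            resid_ss += ((y[sel] - m) ** 2).sum()
            resid_n += sel.sum() - 1
        # self-self slides: observations of zero, inform sigma only
        sel_ref = (slide_tax == reference) & ~np.isnan(y)
        if sel_ref.sum() > 0:
            resid_ss += (y[sel_ref] ** 2).sum()
            resid_n += sel_ref.sum()
        if len(obs_taxa) < 1 or (n_test - len(obs_taxa)) > max_missing_taxa * n_test:
            continue
        k = len(obs_taxa) + 1  # observed taxa including the reference
        mu_ref = -sum(diffs.values()) / k
        mu = {reference: mu_ref}
        mu.update({t: diffs[t] + mu_ref for t in obs_taxa})
        sigma = np.sqrt(resid_ss / resid_n) if resid_n > 0 else np.nan
        se_base = sigma if np.isfinite(sigma) and sigma > 0 else 1.0
        sd = {}
        for t in [reference] + obs_taxa:
            n_t = ((slide_tax == t) & ~np.isnan(y)).sum()
            sd[t] = se_base / np.sqrt(max(n_t, 1))
        kept.append(gene)
        levels.append([mu.get(t, np.nan) for t in all_taxa])
        sds.append([sd.get(t, np.nan) for t in all_taxa])
        sig.append(sigma)

    if not kept:
        raise ValueError("no gene has observations from at least one test taxon")
    lv = pd.DataFrame(levels, index=kept, columns=all_taxa)
    sd = pd.DataFrame(sds, index=kept, columns=all_taxa)
    return BagelEstimate(
        levels=lv,
        level_sd=sd,  # NaN where a taxon was unobserved for the gene
        sigma=pd.Series(sig, index=kept, name="sigma"),
        reference=reference,
    )


def bagel_to_matrix(estimates: BagelEstimate, include_reference: bool = True) -> TaxonGeneMatrix:
    """Taxon x gene matrix of posterior-mean levels.

    The reference row (when requested) is the constrained, extrapolated
    mu_ref — it is zero only if the data make it so.
    """
    df = estimates.levels.T  # taxa x genes
    if not include_reference:
        df = df.drop(index=estimates.reference)
    return TaxonGeneMatrix(
        values=df.copy(),
        provenance="bayes",
        reference=estimates.reference,
        reference_included=include_reference,
    )
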