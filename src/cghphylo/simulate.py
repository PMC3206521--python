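"""Synthetic two-color CGH experiments generated from a known tree.

The generator emulates the study's single-reference design: an
oligonucleotide array designed on the reference taxon (*N. crassa* A in
the study; 10,918 elements), each test taxon hybridized against the
reference in at least quadruplicate with dye swaps, twelve control spots
with no sequence polymorphism, intensity-dependent dye bias, print-tip
block offsets, and flagged/saturated spots.

The divergence model is the one the hybridization proxy rests on: the
expected oriented log2(test/reference) ratio of a present gene falls
roughly linearly with the gene's sequence divergence from the reference,
``E[M] = -k * delta``.  Per-gene divergence is the reference-to-taxon
path length on the generating tree scaled by a Gamma-distributed
per-gene rate (mean 1), giving tunable dispersion of signal across the
array.  Gene loss is an irreversible Poisson death process on the
branches of the tree rooted at the reference: a gene lost on a branch is
absent in every taxon below it, so presence patterns follow exactly the
model class the death-process gene-content distance assumes.  Lost
genes hybridize at background (``absent_shift``).

Everything is reproducible from ``SimConfig.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import STANDARD, SWAPPED, SlideTable, Tree

__all__ = ["SimConfig", "SimTruth", "simulate_divergence", "simulate_slides", "simulate_experiment"]

N_ARRAY_ELEMENTS = 10918  # elements on the full-genome reference array
N_CONTROL_SPOTS = 12  # control spots free of sequence polymorphism


@dataclass
class SimConfig:
    """Knobs of the slide simulator; defaults mirror the study design.

    Attributes
    ----------
    n_genes:
        Array elements including the control spots (default 10,918).
    n_replicates:
        Hybridizations per test taxon (default 4, the study's minimum).
    dye_swap:
        Alternate dye orientation across replicates (half swapped).
    slope:
        log2-ratio lost per unit sequence divergence (``k``).  With the
        default 12, the study's maximum coding divergence of ~10.5%
        depresses the ratio by ~1.3 log2 units.
    noise_sd:
        Per-spot Gaussian sd of the measured log-ratio, in log2 units.
    dye_offset:
        Constant dye bias added to the raw (channel-space) log-ratio;
        it flips sign under orientation correction, so a balanced
        dye-swap pair cancels it exactly.
    bias_amplitude, bias_coefs:
        Intensity-dependent bias added to the raw log-ratio:
        ``amplitude * polyval(bias_coefs, A - mean(A))`` — the smooth
        M-vs-A trend that loess/spline normalization must remove.
    n_blocks, tip_offsets:
        Print-tip blocks (spots split contiguously); optional explicit
        per-block additive offsets.
    loss_rate:
        Gene-loss events per unit branch length (death process).
    absent_shift:
        Mean log2-ratio of a lost gene (signal at background).
    flag_rate, saturation_rate:
        Proportion of spots flagged bad / driven into pixel saturation.
    gamma_shape:
        Shape of the per-gene rate Gamma (mean fixed at 1); smaller
        values give more rate heterogeneity.
    edge_dispersion:
        Granularity of the per-gene Gamma divergence process along
        branches, in events per unit branch length.  A gene's
        divergence on a branch of length l is Gamma-distributed with
        mean l and variance l / edge_dispersion: genes do not diverge
        in lockstep along every lineage, and the branch-level scatter,
        shared by all taxa below each branch, is what leaves a
        tree-shaped covariance signature in the hybridization profiles.
        Small values give sparse, bursty divergence (most genes barely
        change on a branch, a few change a lot); ``numpy.inf`` makes
        divergence deterministic in path length.
    reference:
        Name of the reference taxon (a leaf of the generating tree).
    """

    n_genes: int = N_ARRAY_ELEMENTS
    n_replicates: int = 4
    dye_swap: bool = True
    slope: float = 12.0
    noise_sd: float = 0.25
    dye_offset: float = 0.0
    bias_amplitude: float = 0.0
    bias_coefs: tuple = (1.0, 0.0)  # linear in centered A by default
    n_blocks: int = 16
    tip_offsets: tuple | None = None
    loss_rate: float = 0.0
    absent_shift: float = -3.0
    flag_rate: float = 0.0
    saturation_rate: float = 0.0
    gamma_shape: float = 2.0
    edge_dispersion: float = 5.0
    n_controls: int = N_CONTROL_SPOTS
    reference: str = "N_crassa_A"
    include_self_self: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("loss_rate", "flag_rate", "saturation_rate"):
            v = getattr(self, name)
            if name != "loss_rate" and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per taxon")
        if self.n_controls > self.n_genes:
            raise ValueError("more control spots than genes")
        if self.tip_offsets is not None and len(self.tip_offsets) != self.n_blocks:
            raise ValueError("tip_offsets length must equal n_blocks")


@dataclass
class SimTruth:
    """Ground truth behind a simulated experiment."""

    generating_tree: Tree
    divergence: pd.DataFrame  # gene x taxon, delta >= 0, 0 for the reference
    presence: pd.DataFrame  # gene x taxon in {0, 1}, 1 for the reference
    per_gene_rate: pd.Series
    reference: str
    control_genes: tuple

    def __post_init__(self):
        ref = self.reference
        if not (self.divergence[ref] == 0).all():
            raise ValueError("reference divergence must be zero")
        if not (self.presence[ref] == 1).all():
            raise ValueError("all genes are present in the reference (array design)")
        if (self.divergence.to_numpy() < 0).any():
            raise ValueError("negative divergence")

    @property
    def genes(self):
        return self.divergence.index

    @property
    def taxa(self):
        return list(self.divergence.columns)


def _gene_ids(config: SimConfig) -> list:
    ctrl = [f"ctrl_{i + 1:02d}" for i in range(config.n_controls)]
    rest = [f"g{i + 1:05d}" for i in range(config.n_genes - config.n_controls)]
    return ctrl + rest


def _edges_rooted_at(tree: Tree, ref: str):
    """Edges as (clade away from ref, length); includes the ref stem.

    Deterministically ordered: RNG draws are consumed per edge.
    """
    bl = tree.branch_lengths or {}
    edges = []
    for leaf in sorted(tree.leaves):
        if leaf == ref:
            clade = tree.leaves - {ref}
        else:
            clade = frozenset([leaf])
        edges.append((clade, float(bl.get(leaf, 0.0))))
    for s in sorted(tree.splits, key=lambda s: (len(s), tuple(sorted(s)))):
        clade = s if ref not in s else tree.leaves - s
        edges.append((clade, float(bl.get(s, 0.0))))
    return edges


def simulate_divergence(tree: Tree, config: SimConfig) -> SimTruth:
    """Draw per-gene divergences and presence patterns from the tree.

    delta_gs = r_g * sum over branches e on the reference->s path of
    X_ge, with r_g ~ Gamma(gamma_shape, mean 1) per gene and
    X_ge ~ Gamma(edge_dispersion * length_e, 1/edge_dispersion)
    independent per gene and branch (mean length_e), so E[delta_gs]
    equals the reference-to-s path length times r_g while sister taxa
    share the divergence accumulated on their common branches.
    Control genes have delta = 0 everywhere.
    Presence follows irreversible Poisson loss at ``loss_rate`` per unit
    branch length on the tree rooted at the reference; control genes
    are never lost.
    """
    if config.reference not in tree.leaves:
        raise ValueError(f"reference {config.reference!r} is not a leaf of the tree")
    if tree.branch_lengths is None:
        raise ValueError("generating tree needs branch lengths")
    rng = np.random.default_rng((config.seed, 0))
    genes = _gene_ids(config)
    taxa = sorted(tree.leaves)
    n_g, n_t = len(genes), len(taxa)

    rate = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape, size=n_g)
    rate[: config.n_controls] = 0.0  # polymorphism-free control spots
    col = {t: j for j, t in enumerate(taxa)}
    per_edge = np.zeros((n_g, n_t))
    for clade, length in _edges_rooted_at(tree, config.reference):
        idx = [col[t] for t in clade if t != config.reference]
        if not idx or length == 0:
            continue
        if np.isinf(config.edge_dispersion):
            x = np.full(n_g, length)
        else:
            x = rng.gamma(config.edge_dispersion * length, 1.0 / config.edge_dispersion, size=n_g)
        per_edge[:, idx] += x[:, None]
    delta = rate[:, None] * per_edge

    presence = np.ones((n_g, n_t), dtype=np.int8)
    if config.loss_rate > 0:
        col = {t: j for j, t in enumerate(taxa)}
        for clade, length in _edges_rooted_at(tree, config.reference):
            p_loss = -np.expm1(-config.loss_rate * length)
            if p_loss <= 0:
                continue
            lost = rng.random(n_g) < p_loss
            lost[: config.n_controls] = False
            idx = [col[t] for t in clade]
            presence[np.ix_(lost, idx)] = 0

    rate_s = pd.Series(rate, index=genes, name="rate")
    return SimTruth(
        generating_tree=tree,
        divergence=pd.DataFrame(delta, index=genes, columns=taxa),
        presence=pd.DataFrame(presence, index=genes, columns=taxa),
        per_gene_rate=rate_s,
        reference=config.reference,
        control_genes=tuple(genes[: config.n_controls]),
    )


def gene_blocks(config: SimConfig) -> pd.Series:
    """Contiguous assignment of array elements to print-tip blocks."""
    genes = _gene_ids(config)
    per = int(np.ceil(len(genes) / config.n_blocks))
    blocks = [min(i // per, config.n_blocks - 1) for i in range(len(genes))]
    return pd.Series(blocks, index=genes, name="block_id")


def simulate_slides(truth: SimTruth, config: SimConfig) -> list:
    """Generate the per-spot slide tables for every hybridization.

    Each test taxon gets ``n_replicates`` slides (alternating dye
    orientation when ``dye_swap``); with ``include_self_self`` the
    reference is also hybridized against itself.  The measured raw
    log-ratio of a spot is

        sign * M_bio + dye_offset + bias(A) + tip_offset + noise

    where ``M_bio = -slope * delta`` for present genes and
    ``absent_shift`` for lost ones, and ``sign`` is -1 on a dye-swapped
    slide.  Channel signals are reconstructed from (A, raw M) so a
    round trip through :meth:`SlideTable.oriented_log2_ratio` returns
    the oriented value exactly.
    """
    rng = np.random.default_rng((config.seed, 1))
    genes = list(truth.genes)
    n_g = len(genes)
    blocks = gene_blocks(config).to_numpy()
    base_intensity = rng.normal(11.0, 1.5, size=n_g)  # log2 scale

    taxa = [t for t in truth.taxa if t != truth.reference]
    if config.include_self_self:
        taxa = taxa + [truth.reference]

    slides = []
    for taxon in taxa:
        if taxon == truth.reference:
            m_bio = np.zeros(n_g)
        else:
            delta = truth.divergence[taxon].to_numpy()
            present = truth.presence[taxon].to_numpy().astype(bool)
            m_bio = np.where(present, -config.slope * delta, config.absent_shift)
        for rep in range(config.n_replicates):
            swapped = config.dye_swap and rep % 2 == 1
            sign = -1.0 if swapped else 1.0
            a_vals = base_intensity + m_bio / 2.0
            bias = np.zeros(n_g)
            if config.bias_amplitude != 0.0:
                centered = a_vals - a_vals.mean()
                bias = config.bias_amplitude * np.polyval(config.bias_coefs, centered)
                bias = bias - bias.mean()
            tips = np.zeros(n_g)
            if config.tip_offsets is not None:
                tips = np.asarray(config.tip_offsets, float)[blocks]
            noise = rng.normal(0.0, config.noise_sd, n_g) if config.noise_sd > 0 else 0.0
            raw = sign * m_bio + config.dye_offset + bias + tips + noise
            ch1 = np.exp2(a_vals + raw / 2.0)
            ch2 = np.exp2(a_vals - raw / 2.0)
            flags = np.where(rng.random(n_g) < config.flag_rate, -100, 0)
            saturation = np.where(
                rng.random(n_g) < config.saturation_rate,
                rng.uniform(60.0, 100.0, n_g),
                0.0,
            )
            roundness = rng.uniform(0.7, 1.0, n_g)
            spots = pd.DataFrame(
                {
                    "gene_id": genes,
                    "block_id": blocks,
                    "ch1_signal": ch1,
                    "ch2_signal": ch2,
                    "flag": flags,
                    "saturation_pct": np.round(saturation, 2),
                    "roundness": np.round(roundness, 4),
                }
            )
            slides.append(
                SlideTable(
                    spots=spots,
                    taxon=taxon,
                    dye_orientation=SWAPPED if swapped else STANDARD,
                    slide_id=f"{taxon}_rep{rep + 1}",
                )
            )
    return slides


def simulate_experiment(tree: Tree, config: SimConfig):
    """Convenience: divergence + slides in one call; returns (truth, slides)."""
    truth = simulate_divergence(tree, config)
    return truth, simulate_slides(truth, config)
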