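# Methods

`cghphylo` implements an end-to-end pipeline for building phylogenies
from two-color array-CGH ratio data under a **single-reference
design**: every hybridization pairs a test taxon against the same
reference taxon (the species whose genome the array was designed on),
so all information about a test taxon is its vector of
log2(test/reference) hybridization ratios. The package also ships a
slide simulator so that every stage — and the full
method-combination benchmark — can be run against known ground truth.

## The data model

A spot on a slide carries two channel intensities. We work throughout
with the standard two-color quantities

* `M = log2(test / reference)` — the oriented log-ratio (dye-swapped
  slides are sign-corrected before anything else),
* `A = (log2 ch1 + log2 ch2) / 2` — the mean log intensity.

The biological signal model is the hybridization proxy: for a gene
present in the test taxon the expected oriented log-ratio falls
approximately linearly with the gene's sequence divergence `δ` from
the reference, `E[M] = −k·δ`; a gene lost from the test genome
hybridizes at background, a strongly negative log-ratio.

## The simulator

`simulate.SimConfig` defaults encode the study design being emulated:
10,918 array elements including 12 polymorphism-free control spots,
at least 4 replicate hybridizations per taxon with balanced dye swaps,
one reference taxon, and optional reference self-self slides.

**Divergence.** Per-gene divergence follows a Gamma-process along the
generating tree, viewed from the reference leaf: on a branch of length
`ℓ` a gene accrues divergence `X ~ Gamma(shape = ν·ℓ, scale = 1/ν)`
(mean `ℓ`, variance `ℓ/ν`, independent across genes and branches),
scaled by a per-gene Gamma rate `r_g` with mean 1. Two properties
matter:

* the mean divergence of a gene in taxon `s` equals `r_g` times the
  reference-to-`s` path length, so hybridization level is on average
  the linear proxy for evolutionary distance the method assumes; and
* sister taxa share the divergence drawn on their common branches, so
  taxon profiles carry a tree-shaped covariance signature — the only
  part of the signal from which topology is recoverable at all, since
  expected divergences alone collapse to a one-dimensional
  "distance-from-reference" embedding under the single-reference
  design.

The granularity `ν` (default 5 events per unit branch length) sets how
bursty per-gene divergence is; small `ν` means most genes barely
change on a branch while a few change a lot. The default slope
`k = 12` maps the study system's maximum coding divergence (~10%)
to a ratio depression of roughly 1.2 log2 units, within the dynamic
range of long-oligo arrays.

**Gene loss** is an irreversible Poisson death process on the tree
rooted at the reference: a gene struck on a branch is absent in every
taxon below it, and all genes are present in the reference by array
design (ascertainment). This is exactly the model class the
death-process gene-content distance assumes, which makes its parameter
recovery testable.

**Artifacts.** The measured raw log-ratio of a spot is
`sign·M_bio + dye_offset + bias(A) + tip_offset + noise`, where `sign`
flips on dye-swapped slides (so a balanced swap pair cancels the
constant dye bias exactly), `bias(A)` is a configurable polynomial in
centered `A` (the smooth M-vs-A trend loess must remove), `tip_offset`
is a per-print-tip-block shift, and the per-spot noise is Gaussian
(default sd 0.25 log2 units; the source study does not quantify its
slide noise, so the benchmark sweeps a noise grid instead of trusting
any single value). Flagged and saturated spots are generated at
configurable rates.

**What the simulator does not model:** probe thermodynamics,
paralogous cross-hybridization, spatial artifacts beyond per-block
offsets, and correlated noise between replicate slides. Tests passing
on these data show the estimators are correct under the stated model,
not that real slides satisfy the model.

## Filtering and normalization

`filter_spots` masks flagged, over-saturated and (optionally)
low-roundness spots, and always masks nonpositive channel signals
before the log transform — no pseudocounts. The optional
"40%-present" rule (`filter_presence`) removes genes observed in fewer
than 40% of slides, boundary inclusive. All four normalizations are
per-slide location corrections of M (as a function of A or a
constant); they never touch the mask or the gene universe:

* **linear** — subtract the mean log-ratio of the control spots;
* **lowess** — local *linear* regression of M on A per print-tip
  block (tricube weights, span 0.4, 3 robustness iterations; the
  original instrument software's exact parameters are unpublished, so
  these conventional defaults are configurable);
* **loess** — local *quadratic* regression, whole slide;
* **robust spline** — cubic B-spline (5 df) fitted by iterated
  Tukey-bisquare reweighting per block, with block coefficients shrunk
  toward the whole-slide fit by a precision-weighted average (prior
  weight 20 pseudo-observations). This is a simplified
  empirical-Bayes shrinkage; the reference implementation's internals
  are not published, so equivalence is not claimed.

The local-polynomial smoother is evaluated on an 80-point quantile
grid and interpolated; the degree-1 path is cross-checked against
statsmodels' lowess in the test suite.

## Per-taxon estimation

`summarize_by_taxon` takes the mean or median over a taxon's replicate
slides. The Bayesian route (`bagel_estimate`) fits, per gene, the
linear model `y_slide(s) = μ_s − μ_ref + ε`, `ε ~ N(0, σ²)`, under a
flat prior; the posterior mean is then the least-squares solution, so
the estimates are closed-form. Identifiability is fixed by the
sum-to-zero constraint over the taxa observed for that gene, which
yields an **extrapolated reference level** `μ_ref` without any
self-self hybridization — the architectural reason this estimator is
insensitive to inclusion or exclusion of the reference taxon, in
contrast to plain summaries, whose reference row exists only if
self-self slides do. Only log-scale input is accepted. Genes observed
in fewer than two taxa (counting the reference) or missing more than
half the test taxa are dropped.

## Presence/absence calling

* **Dynamic-cutoff EPP** (`fit_gack`/`gack_binarize`): per taxon, the
  "present" component's density is estimated by locating the mode of
  the value distribution (present genes cluster near zero log-ratio)
  and mirroring its high side; `P(present|v) = min(1,
  present/total)`, monotonized to be nondecreasing in `v`. An EPP
  threshold of `p`% calls conserved every gene with at least a `p`%
  chance of being present (boundary inclusive). Densities come from a
  Gaussian KDE on a 512-point grid; at least 100 values are required.
* **Quartile binning** of Bayesian levels: pooled quartile boundaries;
  presence for values at/above the 75th (Q4), 50th (Q4–Q3) or 25th
  (Q4–Q2) percentile, ties present.
* **MPP-style** (`mpp_binarize`): transform (log passthrough, or
  `arsinh(x) = ln(x + √(x²+1))` on the unlogged ratios), then either
  the EPP machinery on histogram densities — binwidth 0.05 ("norm") or
  the Freedman–Diaconis rule ("exp", whose original definition is not
  recoverable, so this is our documented choice) — or **BPP**: a
  two-component Gaussian mixture fitted by EM, presence called when
  the posterior of the higher-mean component is ≥ 0.5.

All binarizers are location-equivariant and carry provenance
sufficient to reproduce the call bit-exactly at a fixed seed.

## Distances

* **Euclidean** over the genes unmasked in both taxa, with the squared
  distance rescaled by `G/G_shared` so pairs with different
  missingness stay comparable.
* **Correlation**: `1 − Pearson r` over shared genes (≥3 genes with
  variance required).
* **Death-process gene-content distance** (`cgh_death_dist`): with
  `p_i` the fraction of genes called present in taxon `i` and `p_ij`
  the joint fraction, `d(i,j) = ln(p_i·p_j / p_ij²)`. Under
  irreversible loss from the reference ancestor `E[p_i] = e^(−d_i)`
  and `E[p_ij] = e^(−(d_i+d_j−shared))`, so the estimator returns the
  loss-length of the path between `i` and `j`, the shared-stem
  contribution cancelling; the reference is placed by extrapolation,
  `d(i, ref) = −ln p_i`. A pseudocount of 0.5 on present and
  joint-present counts (same count added to the denominator) avoids
  `log 0` while keeping `d = 0` exact when everything is present;
  negative estimates are clamped to zero with a logged warning. This
  is a method-of-moments reconstruction of the death-process model
  class; the original pipeline's likelihood is unpublished and
  equivalence is not claimed.

## Tree building

* **Neighbor-Joining**: Saitou–Nei with the Studier–Keppler Q
  criterion. Negative branch-length estimates are floored at zero
  with the slack moved to the sister edge (the pairwise path length
  through the join is preserved). Verified to reconstruct every
  random additive matrix exactly and cross-checked against
  scikit-bio's NJ.
* **Parsimony**: characters are scored by the two-state
  Fitch/Sankoff dynamic program (exact on multifurcating trees;
  missing calls are wildcards). The search runs `n` random
  stepwise-addition starts, each hill-climbed by nearest-neighbor
  interchange with subtree-prune-regraft moves tried when NNI stalls;
  all distinct best trees are kept. At the study's taxon counts (≤9,
  i.e. ≤135,135 unrooted topologies) an exhaustive mode (`exact=True`)
  is feasible and doubles as the oracle for the heuristic.
* **Consensus**: strict majority rule — exactly the splits occurring
  in *more than* `cutoff` (default 50%) of the input trees; splits in
  exactly half are excluded. Cutoffs below 0.5 are rejected because
  retained splits could then be incompatible.

## Tree comparison

`symmetric_distance` is the Robinson–Foulds symmetric difference of
nontrivial split sets on unrooted topologies (identical topologies 0;
one collapsed branch 1; a two-taxon swap 2); branch lengths are
ignored, and multifurcating consensus trees are compared as-is.
`agreement_subtree_distance` is the minimum number of leaves to prune
for the restricted topologies to coincide, computed exactly by subset
enumeration in increasing deletion size (≤2⁹ subsets at this scale);
any minimizing subset size is reported. When the two trees' leaf sets
differ (±reference comparisons), both metrics first restrict to the
intersection and log it.

## Reference topologies and the benchmark

The MLSA cladogram for the nine-taxon study system is stored as a
newick fixture (`topologies.py`), transcribed from the published
multilocus phylogenies of the group; the nested CON ⊂ NEU ⊂ ALL taxon
sets (six conidiating *Neurospora*; plus *N. terricola*; plus
*Sordaria* and *Podospora*) are obtained by pruning, so restriction
consistency holds by construction. The default generating tree gives
the sets pairwise divergences of roughly 2–7%, ~8% and ~10%,
matching the ranges reported for the real taxa.

`run_benchmark` executes every configured combination — normalization
× estimator × (distance + NJ | discretization + parsimony) — on one
simulated experiment for each taxon set with and without the
reference, scoring each tree by both metrics. Reference handling
reproduces the design contrast: plain summaries include the reference
via self-self slides, while the Bayesian estimator and the
death-process distance use their extrapolated reference values and
never see self-self data. Failing combinations record error rows.
Every stochastic step (simulation, search starts, EM) is seeded from
the config, and a re-run at the same seed is bit-identical.

The original study's empirical recovery percentages depended on
microarray slides that were never deposited; they are not reproducible
and the benchmark does not attempt them. What the synthetic benchmark
does reproduce is the structure of the sweep and the qualitative
behavior (recovery degrades with noise and with evolutionary breadth
of the taxon set; correlation distance tends to underperform Euclidean
here), with all quantitative claims made only about the simulator's
stated conditions.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately modest
sizes chosen to exercise each estimator in its asymptotic regime
without waste: 50,000 genes for death-process parameter recovery
(relative errors ~1%), 5,000 values for mixture separation, 1,000
genes for the Bayesian RMSE check, study-scale arrays (10,918
elements) for the 20-seed end-to-end recovery run, and a
90-row × 2-repeat sweep for the determinism check. Ties at binning
boundaries are always called present, matching the inclusive EPP
rule; KDE bandwidths are scipy's Scott default; the NJ implementation
rejects asymmetric input rather than symmetrizing silently.

## Known limitations

* The GACK, MPP and robust-spline reconstructions follow the
  published *descriptions*, not the original binaries; parameter-level
  agreement with those programs is not claimed.
* The mirrored-mode EPP estimator assumes the present component is
  the distribution's modal component; it will miscall datasets where
  most genes are absent.
* `agreement_subtree_distance` enumerates subsets and is meant for
  ≤ ~12 leaves, as is the exhaustive parsimony mode.
* The Bayesian estimator returns point estimates (closed-form
  posterior means); credible-interval machinery of the original
  expression-analysis tool is out of scope.
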