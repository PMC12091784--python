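# Methods

`erainv` implements a four-phase workflow for optimizing ERα-targeted
compounds from tabular QSAR data: explainable descriptor selection,
bioactivity regression, multi-endpoint ADMET classification, and
genetic-algorithm inverse design with nearest-compound decoding. This note
documents the models, the numerical choices, and what the synthetic data
generator does and does not emulate.

## Problem setting

The input is a table of compounds (identified by SMILES strings, treated as
opaque keys) with several hundred numeric molecular descriptors, a potency
measurement (IC50 in nM, modeled as pIC50 = 9 − log10 IC50), and five binary
ADMET endpoints: Caco-2 permeability, CYP3A4 metabolizability, hERG channel
interaction (1 = cardiotoxic), human oral bioavailability, and micronucleus
genotoxicity (1 = genotoxic). Descriptors belong to named families (atom
counts, topological indices, electrotopological states, ...) which serve as
the grouping unit for group-level selection.

## Phase 1 — descriptor selection

**Per-descriptor importance** is the mean absolute Shapley attribution of a
boosted-tree regressor fit on all descriptors. Attributions use the
*interventional* value function: f_S(x) is the mean model output with the
features outside S replaced by background rows (at most 100, subsampled
deterministically). For additive tree ensembles the package computes these
attributions exactly in polynomial time from the flattened leaf structure:
for a leaf reachable only when the features in A take x's values and the
features in B take the background row's values, a feature in A receives
leaf_value·(|A|−1)!·|B|!/(|A|+|B|)! and a feature in B the negated
symmetric weight. Summing over leaves and averaging over background rows
reproduces subset enumeration to machine precision and satisfies local
accuracy (base + Σφ = prediction) exactly. A brute-force enumeration oracle
(≤ 15 features) is kept for verification and as the fallback for non-tree
models.

The importance model subsamples columns per tree (`colsample_bytree = 0.3`,
300 trees). Without this, gradient boosting routes all splits through a
single representative of each correlated descriptor family and the family's
other members receive exactly zero interventional attribution; per-tree
column subsampling is the standard decorrelation device (the same mechanism
random forests use) and spreads attribution across a family in proportion to
its redundancy. Downstream predictive fits use package defaults.

**Group-level importance** comes from LassoNet: a two-hidden-layer ReLU
network (widths 64, 32) with a linear skip layer θ, trained to minimize
L(θ, W) + λ‖θ‖₁ subject to the per-feature hierarchy bound
‖W_j^(1)‖∞ ≤ M·|θ_j| with M = 10. Training is full-batch Adam
(lr 2·10⁻²); after every step the (θ_j, W_j^(1)) pairs are projected by the
hierarchical proximal operator, solved in closed form, which produces exact
zeros and satisfies the bound exactly (the first-layer row is capped by
M|θ_j| after rounding, so the constraint holds in floating point, not just
analytically). The path is dense-to-sparse and warm-started: a geometric
grid of 50 penalties anchored at 2% of the dense fit's skip-gradient
magnitude, extended geometrically (at most twice over) until the support
empties. Each feature gets λ_drop(j), the smallest penalty at which θ_j is
zero and stays zero; survivors of the whole extended path get one geometric
step beyond it.

A group's score is the mean λ_drop of its **top three** members. Descriptor
taxonomies are heavily skewed — in real descriptor sets one family can hold
two-thirds of the columns — and a full-group mean would drown a few
informative members among inert siblings; representing a family by its
strongest members matches how the families are actually summarized
downstream.

**Selection rule.** The candidate set C is the Shapley ranking restricted to
scores above 10⁻¹² (floating attributions are rarely exact zeros). A count
sweep refits the regressor on the top-k of C for k on the arithmetic grid
2, 5, 8, …, 290 (97 values; truncated when |C| is smaller) over replicated
train/test resamplings, and the chosen count is the smallest k whose mean
R² is within δ = 0.01 of the grid maximum — a formalization of "more
descriptors stop helping". The final list of 50 takes the two top-Shapley
members from each of the five best LassoNet groups ("group-quota" picks,
recorded in provenance) and fills the remainder from the global Shapley
ranking ("global-rank"), deduplicated, with ties broken by descriptor name.

**Validation** ("independent variable perturbation analysis") refits the
regressor on five 50-descriptor strata — ranks 1–50, 51–100, 101–150, a
random 50 from the entire set, and a random 50 from the complement of C
(falling back, with a warning, to the 50 lowest-ranked when the complement
is smaller) — over replicated splits. The two random strata are redrawn
every replicate with replicate-derived seeds; a single draw would make the
stratum mean hostage to one selection. The report carries per-stratum R²
distributions, a one-sided Mann–Whitney test of stratum 1 versus stratum 5,
and a monotonicity verdict: a step up the sequence counts as a violation
only if it exceeds twice the pooled replicate spread. The spread (not the
standard error) is the right yardstick here because the random strata are
legitimately noisy objects — their replicate distribution includes selection
randomness — and because a random draw from a sparse-signal table can
contain a few genuinely informative descriptors, which puts its expectation
slightly above the mid-rank strata no matter how many replicates are run.

## Phase 2 — bioactivity regression

Five families behind one interface: LightGBM (`gbt_a`, the default),
XGBoost (`gbt_b`), random forest, an MLP and an RBF-SVM (both behind a
standardization pipeline), plus a plain linear baseline for comparisons.
Metrics are computed from their defining formulas (R² = 1 − SSE/SST, MSE)
and cross-checked against scikit-learn in tests; a zero-variance target
raises an error rather than returning NaN, since silent NaNs poison
replicate summaries. Family comparison resamples the 0.7/0.15/0.15 split on
every replicate (20 by default), which is what makes the reported standard
deviations meaningful. Sensitivity analysis exposes per-descriptor
dependence profiles: the descriptor's raw values paired with its per-sample
attributions, plus its rank by mean |φ|.

## Phase 3 — ADMET classification

"Multi-output" mode is an XGBoost classifier per endpoint managed behind a
single interface with one shared seed; "single-output" mode is five
independent LightGBM fits with per-endpoint derived seeds. Both expose
probabilities; the label is 1 iff the probability strictly exceeds 0.5 (a
probability of exactly 0.5 maps to 0). ROC-AUC uses the rank (Mann–Whitney)
formulation with ties counting ½. The two modes are compared per endpoint
with a two-sided Mann–Whitney U test on replicate accuracies: exact p by
enumeration of all rank assignments (tie-aware, midranks) when both samples
have ≤ 8 observations, otherwise the normal approximation with tie and
continuity corrections.

## Phase 4 — GA inverse design

The search space is [0,1]^d, the min-max-normalized descriptor box learned
from the training rows (constant columns map to 0; decoding clips, so every
genome decodes to descriptor values inside the training range). Fitness is

    f̂(x) − w · max(0, t − Σ_k ĝ_k(x)),

where f̂ is the trained regressor, ĝ_k are the five ADMET predictions
*recoded for favorability* — Caco-2, CYP3A4 and HOB count their raw label,
hERG and MN count its absence, since 1 codes cardiotoxic/genotoxic there and
summing raw labels would reward toxicity — t is the ADMET threshold
(default 3 of 5; the constraint is Σĝ ≥ t on thresholded labels, consistent
with the strict 0.5 rule), and w is a static penalty weight (default 20,
comfortably above the pIC50 range so no infeasible individual can outrank a
feasible one). The GA is generational with elitism 1: tournament selection
(size 3), uniform crossover at rate 0.8, per-gene Gaussian mutation
(σ = 0.1, clipped to the box) at rate 0.85 early and 0.5 after the scheduled
switch generation — the high early rate buys exploration, the lower late
rate exploitation once the search saturates. Defaults are population 500
for 5000 generations with the switch at 2000; a desk-scale profile
(population 100, 300 generations) is provided for quick runs and tests.
All randomness flows from one integer seed; the best-so-far trace is
recorded every generation and is non-decreasing by construction.

Because a descriptor vector rarely corresponds to a synthesizable molecule,
the optimum is interpreted through its k nearest real compounds by Euclidean
distance in normalized space (computed without clipping, so genuinely
out-of-range compounds are not artificially pulled closer), ties broken by
row order.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, with
full ground truth stored for recovery tests. Design, with defaults chosen
to sit in the regimes the real-data workflow reports:

- **Design matrix**: n = 1500 compounds × d = 200 descriptors in 20 named
  groups; within-group correlation 0.5 through a shared group factor,
  between-group correlation 0; columns rescaled to positive ranges with
  random per-column scales. Group sizes are skewed: the signal-bearing
  groups (2 by default) jointly hold 75% of the columns, mirroring real
  descriptor taxonomies where a few families dominate the table. This
  skew is what gives the importance ranking a realistic middle class of
  correlated, partially informative columns instead of a sparse-signal
  cliff.
- **Activity**: exactly `n_informative` (10) descriptors, split across the
  signal groups, carry nonzero coefficients on their standardized values;
  coefficient magnitudes are Uniform(0.5, 1.5) with a coherent sign per
  group (a descriptor family pushes potency in one direction — random signs
  would cancel the shared factor and make family members useless proxies).
  One pairwise interaction and one hinge term, each sized to ~15% of the
  linear variance, make the truth nonlinear enough that tree ensembles beat
  linear fits. The result is mapped to a realistic pIC50 scale (mean ≈ 6.5,
  signal SD ≈ 1.2).
- **Noise**: Gaussian, with SD derived (unless given) from a target signal
  variance fraction of 0.8 — so the best attainable R² is 0.8 and a
  boosted tree realizes roughly 0.6–0.75, the band the workflow reports on
  real data.
- **ADMET labels**: per endpoint, a logit over six standardized descriptors
  (half reused from the informative set, fraction configurable) scaled to
  SD 8 plus standard logistic noise; the intercept is resampled (up to 100
  times) until prevalence lands in [0.2, 0.8]. Labels are learnable to
  held-out accuracy ≈ 0.82–0.91 on all descriptors. Accuracy is lower when
  the classifier sees only the activity-selected 50 descriptors, because
  half of each endpoint's drivers lie outside the activity-informative set
  by construction — the deliberate feature that makes the GA's constrained
  optimum differ from the unconstrained one.

What the generator does **not** emulate: real descriptor marginals (integer
counts, zero inflation), the ambient redundancy of real chemistry where
almost any 50 descriptors predict moderately well, structure–activity
cliffs, or any relationship between the placeholder SMILES strings and the
descriptor values. Passing recovery tests therefore show that the selection
machinery finds planted structure of the assumed form — not that it would
rank any particular real descriptor family highly.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit integer seed; there is no
global random state. The pipeline fans a single seed into fixed per-phase
offsets and serializes its configuration into a run manifest from which an
identical run can be reproduced. Replicate loops derive per-replicate seeds
as base + index. CSV output uses 17-significant-digit floats and round-trip
parsing, so written tables reload bitwise-equal.

The test suite and the acceptance script run everything at desk scale on one
CPU: the study-size dataset (1500 × 200) for recovery, validation and sweep
checks (the sweep on a truncated grid with the same spacing), and reduced
GA profiles for the analytic surrogate checks; the paper-scale GA
(500 × 5000) is exercised by the acceptance script itself.

## Known limitations

- LassoNet training is full-batch Adam with a fixed iteration budget per
  path point; very ill-conditioned inputs may need a smaller learning rate.
  Standardization is applied internally by default.
- Interventional tree attribution is exact but O(leaves × samples ×
  background × depth); rankings on large tables should use the built-in
  deterministic subsampling (defaults: 512 explained rows, 100 background).
- The multi-output ADMET model treats endpoints as independent given the
  descriptors; no multi-label dependence is modeled.
- Descriptor vectors found by the GA are interpreted only through nearest
  real compounds; no molecular structure is generated.
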