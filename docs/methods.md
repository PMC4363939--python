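# Methods

## Data model

Expression enters the pipeline as probe-level log2 ratios of each treatment
group against the normal-diet (ND) control, per tissue, group and week:
three replicate values, their geometric mean (the arithmetic mean in log2
space) and a two-tailed t-test p-value. Because the ratios are taken
against ND, the control's own log2 ratios are identically zero and ND rows
of any design matrix are zero-filled rather than drawn from a master list.

Phenotypes are one value per (group, week): body weight (g), blood glucose
(mg/dl), eight pro-inflammatory cytokines (GM-CSF, IFNγ, IL-1a, IL-1b,
IL-6, MCP1, TNF-α, IL-12p70) and three anti-inflammatory cytokines (IL-4,
IL-10, IL-13).

## Noise filtration

A log2 ratio x is *up*-regulated when x > 1, *down* when x < −1 (strict
inequalities; exactly ±1 is insignificant). A probe survives filtration iff
all three replicates fall in the same class; unanimously insignificant
probes are dropped by default (`keep_insignificant` retains them), since
the master list is meant to hold significantly perturbed, noise-free genes.
Genes measured by several probes collapse to the probe with the smallest
p-value; exact ties break to the lexicographically smallest probe id so
results are order-independent. The surviving gene-level table per week is
the master list; the gene's expression is the retained probe's geometric
mean (the value its p-value refers to).

## Design assembly

Two early weeks (3 and 6) supply predictors as separate observation rows —
one row per (group, input week) — so a blind group later yields one
prediction per input week. Columns are either the genes common to every
non-control (group, week) master list (*intersection*) or present in any
of them (*union*), with absent entries marked missing. Responses repeat
each group's phenotype at the critical output week across that group's
rows: week 15 for body weight, week 12 for glucose, and for the cytokine
panels weeks 9 and 12 jointly, as parallel response columns (one per
cytokine per output week, 16 pro- and 6 anti-inflammatory responses). The
row-stacked alternative for combined cytokine weeks was considered and
rejected: per-week predictions of every cytokine at both output weeks
require the column layout.

Training groups default to ND, HFHSD, KAL-20 and KAL-75 with KAL-5 held
out. Including ND (all-zero expression, control phenotype) anchors the
healthy end of the response range; `include_control=False` reproduces the
three-group alternative.

## PLS engine

The regression core is NIPALS PLS with mean-centering and unit-variance
scaling (ddof = 1), chosen over SVD-based solvers because NIPALS extends
to incomplete data through available-data projections: weights, scores and
loadings are computed over observed entries only, and deflation touches
only observed cells. The union protocol and blind prediction rely on this.
On complete data the implementation agrees with an independent reference
PLS to ~1e-7 relative when both are converged tightly (the package default
tolerance is 1e-12 on the weight vector; single-response weights are
closed-form). Zero-variance columns are dropped with a warning. Prediction
estimates scores sequentially with deflation, so a fully missing row
predicts the training response mean.

Diagnostics follow the SIMCA conventions: R²X and R²Y are cumulative
explained-variance fractions in the scaled space; Q² = 1 − PRESS/SS from
k-fold cross-validation (default 7 folds, round-robin assignment after a
seeded shuffle), computed cumulatively per component on responses scaled
by the full-data standard deviation so multi-response panels weigh each
response equally. The component count grows while the marginal Q² gain
exceeds 0.01, capped at min(n−1, p, 10), and is never fewer than one; the
reported diagnostics are evaluated at the chosen size. Both the fold count
and the 0.01 rule are documented package defaults, not claims about any
proprietary implementation.

VIP for predictor j is

    VIP_j = sqrt( p · Σ_a SS_a (w_aj / ‖w_a‖)² / Σ_a SS_a )

with SS_a the response sum of squares explained by component a, so the
squared scores average to one and VIP > 1 marks above-average influence —
the default selection cutoff. Selection keeps VIP > cutoff and refits,
re-choosing the component count on the reduced matrix. With few
observations and many exchangeable noise predictors this cutoff is a
high-recall, low-precision rule: planted signature genes are recovered
nearly completely, but the selected set also contains noise genes whose
small-sample correlations clear the relative threshold. The predictivity
gate (Q² > 0.5) is what certifies a signature, not the selection alone.

## Formulation evaluation

The affine map from a new experiment's phenotype scale to the reference
scale passes through the two experiments' (ND, HFHSD) anchor pairs:
m = (ref_HFHSD − ref_ND)/(new_HFHSD − new_ND), c = ref_ND − m·new_ND. The
anchors (27.5, 38) g and (141, 170) mg/dl against (28, 31) g and
(138, 158) mg/dl give (3.5, −70.5) and (1.45, −59.1). Written as
y = mx + c the defining equations read in the opposite direction; the
implementation follows the direction consistent with the published
parameter values and converted observations. Externally supplied (m, c)
are accepted because a second published experiment's parameters are not
reproducible from its stated anchors under either direction.

Reference ranges sit at 25% and 50% of the ND→HFHSD gap; classification is
`+` for values at or below the 25% point, `+/-` up to the 50% point, `-`
above. Boundary values go to the milder class, because the disease class
is defined strictly as "more than" the upper cutpoint. Converted values
are reported at full precision and rounded to 2 decimals only for display.

## Network statistics

Edges come from a STRING-style export filtered to the experimental
evidence channel with score ≥ 1 by default (i.e., any direct experimental
support); symmetric duplicates collapse to the better-scored edge and
self-loops are dropped. The graph holds all signature genes (annotated
with every parameter whose signature contains them; multi-parameter nodes
are flagged) plus first-neighbour interactors.

Module statistics follow the Cytoscape NetworkAnalyzer definitions, frozen
here so results are implementation-independent: density 2E/(n(n−1)),
average neighbours 2E/n, centralization [n/(n−2)]·[k_max/(n−1) − density]
(undefined below 3 nodes and reported as missing), heterogeneity
sd(k)/mean(k) with population variance, and the mean local clustering
coefficient. The power-law exponent of P(k) ∝ c·k^(−γ) is fit by ordinary
least squares on log P(k) vs log k over observed degrees ≥ 1 — the
classical recipe, exact on noiseless synthetic counts — with a discrete
zeta-normalized maximum-likelihood estimator available behind
`method="mle"`. Hubs are the max(1, floor(n·fraction)) highest-degree
nodes of a module, ties broken by degree then lexicographic id, with local
clustering reported alongside since intra-module hubs are expected to
cluster tightly. Published hub counts round inconsistently across modules;
the floor rule is this package's single documented convention, not a
reproduction claim. Functional modules are induced subgraphs over a
user-supplied gene→process annotation table (an enrichment-tool export);
no live database or enrichment service is queried.

## Synthetic data generator

The generator emulates the study design: groups ND, HFHSD and three
treatment doses (KAL-5/20/75), weeks 3–18 in steps of 3, three replicate
arrays, n_genes ≫ observations. Each non-control group carries a disease
severity (HFHSD 1.0, KAL-5 0.8, KAL-20 0.55, KAL-75 0.3, custom groups
seeded from U(0.3, 1.1)) chosen so treatment dose monotonically attenuates
the signal while keeping most signature genes above the two-fold
threshold. Signature genes get expression d·a·severity (direction d = ±1,
magnitude a ~ U(3.5, 5)) plus per-(gene, group, week) biological variation
(`gene_wiggle_sd`, default 0.15 log2 units); non-signature genes are
exchangeable N(0, 0.45) noise, so a small realistic fraction crosses the
threshold and survives filtration. Replicates add N(0, noise_sd) in log2
space — additive Gaussian noise being the simplest model consistent with
log-ratio data — and probe p-values are U(0, 0.05) (only their ordering
matters for dedup).

Phenotypes follow logistic trajectories that plateau exactly at each
phenotype's critical week (15/12/9); a group's deviation from the ND
baseline is an exact linear function of its signature genes' mean week-3/6
expression, with coefficients normalized so full severity reproduces
plateau gaps of +10.5 g weight, +29 mg/dl glucose, +50% pro- and −35%
anti-inflammatory cytokines — the reference experiment's ND/HFHSD
contrast. Phenotype measurement noise scales with `noise_sd`, so at
noise_sd → 0 (and wiggle 0) phenotypes are exactly linear in planted
expression, which the recovery tests exploit. Duplicate probes re-measure
a gene with independent noise and p-value; inconsistency corruption gives
a probe a clearly regulated value and flips one replicate's sign,
guaranteeing mixed classes. Corruption targets only non-signature probes
so planted recoverability — a generator invariant — cannot be destroyed by
its own pathology knobs.

What the generator does **not** emulate: raw probe intensities, array
normalization and batch effects, probe-to-gene annotation error,
within-group animal variation in phenotypes (one value per group/week, as
in the study's tables), and nonlinear gene–phenotype links. Passing tests
therefore demonstrate correctness of the pipeline's statistics under the
planted linear model, not biological validity on real arrays.

## Problem sizes and determinism

Tests and the demo run at a few hundred genes, 8–12 signature genes and
the 8-row training design — the same observation count as the real study,
with the gene count scaled to keep the full suite fast. Statistical
acceptance checks use 50–100 seeded replicates. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); identical
(design, seed) pairs reproduce outputs byte-for-byte, and the CLI records
seeds and parameters in each run's manifest.

## Known limitations

- With missing data, score orthogonality and the Q²/R² identities hold
  only approximately; they are exact on complete data.
- The union protocol can produce rows or columns with no observed entries
  (e.g., an empty master list); these are rejected with an error rather
  than imputed, and the training driver records the protocol's failure.
- The log–log OLS power-law fit is biased on small noisy networks; it is
  kept as the primary method for comparability with the era's literature,
  with the MLE as the principled alternative.
- VIP selection with cutoff 1.0 controls recall, not false discoveries; no
  multiplicity correction is attempted at n = 8.
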