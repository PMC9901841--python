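# Methods

## Assay conversion

The permeability equation implemented in `pampanet.pampa` uses the printed
constant 2.303 (the usual decimal-log conversion factor) rather than ln 10
to full precision, and treats the inner bracket
1 − ((1+r_v⁻¹)/(1−R_M))·C_A(t)/C_D(0) as valid only strictly inside (0, 1).
Outside that range the closed-form solution of the two-compartment
diffusion model no longer describes the experiment (equilibration or
impossible mass balance), and the code raises a typed error rather than
returning a number. C_A(t) = 0 is a distinct "no detectable permeation"
signal: Pe is exactly 0, logPe is undefined, and downstream tables label
the well instead of carrying −∞.

Two conventions exist for the membrane retention ratio. The form used by
default is R_M = 1 − (C_D(t)/C_D(0) − V_A·C_A(t)/(V_D·C_D(0))); a strict
mass-balance derivation instead subtracts the acceptor term,
R_M = 1 − C_D(t)/C_D(0) − V_A·C_A(t)/(V_D·C_D(0)). Both are exposed
(`convention="printed" | "mass_balance"`); the package takes no position
on which a given laboratory intends, so callers converting real plate
data should check their assay protocol.

The −6.2 classification cutoff is inclusive: logPe = −6.2 is "higher"
permeability. The cutoff is specific to pH 7.4 and the standard
experimental setup; it is a parameter everywhere it appears.

## Descriptors

The descriptor engine is RDKit. The default backend computes the full 2D
descriptor set (~210 descriptors spanning topological, constitutional,
electronic and hybrid families, including BCUT2D). An optional 3D backend
embeds a single ETKDG conformer per molecule with a fixed seed and appends
the RDKit 3D shape descriptors; these are conformer-dependent and should
be interpreted as such. Descriptor values RDKit cannot evaluate are stored
as NaN and removed by whole-column screening before modelling — the
simplest policy that keeps the design matrix dense; per-cell imputation
was deliberately avoided because missingness here is structural (a
descriptor undefined for a molecule class), not random.

CDK-style descriptor names common in the permeability literature
(nHBDon, TopoPSA, XLogP, nAcid, BCUTw/c/p, …) are mapped to their nearest
RDKit counterparts in `chemdata.CDK_NAME_MAP`. The mapping is semantic,
not numeric: different engines produce different values for the same
descriptor concept, and CPSA-family descriptors (FNSA.3) and a few others
have no RDKit analogue. Reproducing any particular engine's descriptor
counts is therefore out of scope; what matters to the method is the
descriptor semantics feeding the selection and regression stages.

## Scaling

Features are normalised to [0, 1] by per-column min–max parameters fitted
on the training table only and applied unchanged to test/external/new
data. Out-of-range values on new data are **not** clipped: a scaled
descriptor far outside [0, 1] is exactly the kind of extrapolation signal
the applicability domain should see. Columns constant in training map to
0. The regression target is min–max scaled internally by the same rule
(inverted at prediction time); this keeps the logistic hidden units in
their responsive range regardless of the logPe span of the dataset.

## Data partitioning

`split_dataset` draws the external validation set first, then the test
set, uniformly at random with a seeded generator. Sizes are explicit
counts, not percentages — the historical protocol's 141/33/16 split of a
190-molecule table is not recoverable from "80/20" arithmetic
(0.8 × 174 = 139.2), so the printed sizes are the defaults.

## Feature selection

RFE with random-forest importance under repeated K-fold CV. Inside every
resample the forest is fitted on the analysis part only and descriptors
ranked (impurity importance by default; permutation importance
available — the two rarely disagree on these data shapes and impurity is
an order of magnitude cheaper). Each candidate subset size is refitted on
its top-ranked descriptors and scored by RMSE on the held-out fold; sizes
are compared on fold-averaged RMSE with ties broken toward the smaller
subset. Because the ranking is recomputed inside each resample, the
selection cannot exploit validation data; the test suite enforces this
with a leak canary (a descriptor equal to the outcome only on one fold's
validation rows must not improve RMSE_cv). The candidate grid defaults to
a geometric sequence {1, 2, 4, …, p}. Forests default to 500 trees;
selected outcomes on a given dataset can be pinned to an explicit
manifest file to bypass stochastic re-selection.

## Rprop+ training

Weights are initialised from a seeded standard normal. The optimiser is
canonical Rprop+ with per-weight step sizes: grown by η⁺ = 1.2 on a
stable gradient sign, shrunk by η⁻ = 0.5 on a sign flip with the previous
update reverted and the stored gradient zeroed, clamped to
[10⁻⁶, 50], initial step 0.1. Training stops when the largest absolute
partial derivative drops below 0.01 (default) or at the step cap. These
constants are the standard Riedmiller–Braun values used by the common
reference implementations of the algorithm. The error function keeps the
½ factor, so reported final errors follow the ½·Σ(o−y)² convention.

The output unit is linear. A logistic output cannot reach the boundaries
of the scaled target range without saturating, and regression on a
bounded but continuous target is the standard configuration for this
architecture. Training is full batch — the datasets this package targets
are a few hundred rows — and bit-reproducible for a fixed
(seed, data, config) triple.

## Stacking and the applicability domain

The two base networks are trained on the full training table; the meta
network is trained on their predictions with the experimental values as
target. Two meta-feature modes exist:

* `resubstitution` (default): meta features are the base models'
  predictions on their own training data. This matches the historical
  protocol for this model family and relies on the bases overfitting the
  training table; its resubstitution statistics are diagnostics of that
  overfit, not performance estimates.
* `out_of_fold`: meta features are cross-validated predictions, the
  statistically safer choice when the ensemble is meant to be tuned on
  its own training signal.

Per-molecule reliability is the sample SD of the base predictions (in
logPe units, computed before the meta layer); the domain threshold is
3 × the maximum training-set SD, so every training molecule is inside the
domain by construction. Out-of-domain molecules are predicted and
flagged, never dropped. With only two base models the SD reduces to
|y₁−y₂|/√2; the machinery accepts any number of bases ≥ 2.

Divergent training (non-finite error) is retried once with a fresh seed
and then raised; folds are never silently skipped.

## Baselines and interpretation

`fit_linear_baseline` fits OLS with intercept on a small descriptor
subset under the same CV plan and holdout protocol as the networks, as a
variance-explained reference. `surrogate_tree` fits one CART regression
tree on standardised (centred/scaled) descriptors with a readability-
oriented default complexity (depth 4, ≥5 molecules per leaf, giving a
tree of roughly a dozen leaves); each leaf reports its mean logPe, member
count, percentage and higher/lower class at −6.2. The tree is an
interpretive device, not a predictor — its splits depend on the
descriptor backend and are not asserted against any reference tree.

## Cross-validated reporting

A statistic labelled "cv" is computed on each validation fold and
averaged across all folds and repeats. "Resubstitution" applies the
final model to its own training data; "holdout" applies it to data not
used in fitting. The fold-level RMSE vectors of two base models under a
shared plan are compared by Pearson correlation — low correlation
indicates complementary errors and a stacking opportunity.

## Relative Gini (gain-curve) score

Items are sorted by prediction, best first; the cumulative share of the
outcome is traced against the cumulative share of items, and the area
between the curve and the diagonal is divided by the same area for the
outcome-sorted ideal ordering. Outcomes are translated by their minimum
before accumulation, making the curve well defined for all-negative
quantities like logPe while leaving the perfect-sort score at exactly 1.
Tied predictions are pooled into straight segments (equivalent to
averaging over all within-group orderings), so a constant predictor
scores exactly 0 and an anti-sorted predictor scores negatively.

## Synthetic data

The generator emulates the statistical shape of a curated PAMPA QSAR
table: default 190 molecules × 60 descriptors, 5 informative columns,
5 zero-variance columns, an 8-column block with pairwise correlation 0.9,
and logPe = −6.2 + 0.9·signal + N(0, 0.15²). The signal combines a linear
term, one pairwise interaction and one saturating tanh nonlinearity and
is standardised before scaling, so roughly half the molecules fall on
each side of the −6.2 cutoff and a nonlinear model has headroom over a
linear baseline. The spread (0.9) and noise (0.15 log units) were chosen
to give logPe ranges of roughly −8.5…−4.5 and a noise floor small
relative to the signal, the regime typical of curated PAMPA datasets.
Bookkeeping exposes the noise-free signal, so the Bayes-optimal R² is
computable for every generated dataset and fitted models can be checked
against it.

Synthetic PAMPA plate measurements are produced by inverting the
permeability equation: concentrations are solved so the forward
conversion recovers the requested logPe exactly at the requested
retention. Requests are rejected when the inner bracket would fall
outside [10⁻⁶, 1−10⁻⁶]; beyond that window the measurement is physically
uninformative for the given incubation (fully equilibrated or below
detection) and the floating-point round trip degrades.

What passing on synthetic data does **not** show: robustness to real
descriptor collinearity structure, assay noise heteroscedasticity, or
chemistry-specific failure modes (tautomers, charge states) — the
generator's columns are Gaussian features, not molecules.

## Problem sizes in the test suite

The test suite and acceptance checks run the full algorithms at reduced
scale — smaller networks (e.g. 8-4 / 12-6 hidden units), 4–5-fold CV with
one repeat, forests of 30–100 trees, and synthetic tables of 120–190
rows — sizes chosen so the whole suite exercises every code path in
about a minute while leaving the statistical properties under test
(signal recovery, stacking dominance, leak-freedom, overfit signatures)
clearly resolvable. The paper-regime check uses the protocol geometry
itself: a 141-row training table with the 20-15-5 / 30-20-10 / 2-1
architectures.

## Known limitations

* The applicability domain sees only base-model disagreement; a molecule
  on which both bases are confidently wrong passes the domain check.
* With the default resubstitution stacking, cross-validated statistics of
  the *ensemble* are optimistic; use `out_of_fold` when an honest CV
  estimate of the stacked model itself is needed.
* Descriptor values are engine-specific; models are only portable
  together with their descriptor manifest and backend provenance.
* No pH-dependence: the −6.2 rule and any trained model apply to the
  measurement pH only.
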