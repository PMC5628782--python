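# Methods

## Generative model

The simulator implements the canonical incidence/progression causal
diagram for a case-only study. Per individual, independently:

- `A ~ Binomial(2, maf_a)` — a biallelic variant affecting incidence only,
  additively coded (the standard GWAS convention; the per-allele effect is
  a log-odds of `log(or_a_incidence)`);
- optionally `B ~ Binomial(2, maf_b)` — a variant affecting progression
  only, used as the negative control for selection bias;
- `C ~ N(0, 1)` — a measured confounder of incidence and progression;
- `U ~ N(0, 1)` — an unmeasured confounder (one by default; a list of
  `(OR, β)` pairs generates several independent U's);
- disease `D ~ Bernoulli(expit(α + Σ log-OR · covariate))` — logistic,
  because odds ratios are the stated effect scale;
- progression `Y = β_A·A [+ β_B·B] + β_C·C + β_U·U + ε`,
  `ε ~ N(0, residual_sd²)` — generated for everyone, defined as observed
  only among cases. Full-cohort progression fits are exposed as a
  simulation-only oracle and labelled as such.

Default parameters: `maf_a = 0.2`, incidence ORs of 1.3 per allele of A
and per SD of C, `β_A = 0`, `β_C = 0.1`, prevalence target 0.2,
n = 50,000 per replicate, 500 replicates. The four confounding presets
set `(OR_U, β_U)` to (1.5, 0.5), (2, 0.8), (2.5, 1), (3, 1.5).

### Intercept calibration

The marginal prevalence `E[expit(α + η)]` has no closed form when η mixes
binomial and normal components, so α is found by Brent root search on the
mean predicted risk of a fixed 10⁶-individual calibration draw
(tolerance ±0.005). The calibration seed is a package constant, distinct
from the simulation master seed: the intercept is a function of the
science parameters only, and every replicate of a scenario shares it.
Failure to bracket the root or to reach the tolerance raises a
`CalibrationError` naming the bracketing interval.

### Seeding

Replicate r of a scenario uses
`SeedSequence(entropy=master_seed, spawn_key=(r,))`, a counter-based
scheme: replicates are mutually independent, each is individually
reproducible, and runs are bit-identical for identical (config, seed).

### Residual SD of progression

`residual_sd` is the one generative parameter without a stated value. It
does not move the expected case-only slopes (the bias is a projection of
the systematic part of Y), but it scales every model SE and therefore the
CI coverages. We calibrated it against the reference per-cell SEs of the
case-only fits at ≈10,000 cases — A row 0.01/0.02/0.02/0.03, C row
0.01/0.01/0.01/0.02 across the four presets. All eight printed SEs are
reproduced (at 2-decimal rounding) only for `residual_sd` in roughly
[0.63, 0.74]; the default is **0.65**. Values outside that window break
at least one printed SE (e.g. 0.5 gives 0.02 for A/strong where 0.03 is
expected).

## Estimation

Case-only estimates are univariable OLS slopes among cases (two separate
fits for A and C, matching the two separate summary rows; a `joint_fit`
switch fits them jointly — numerically the two differ by <0.002 here).
CIs are normal-quantile Wald intervals with z = 1.96 exactly; at ~10⁴
cases the t correction is negligible. Across replicates we report the
mean coefficient, the empirical SD of coefficients, the mean model SE
(the "(SE)" of the summary table; the empirical SD is also reported so
either reading can be checked), and coverage = % of replicate CIs
containing the truth. Replicates with fewer than 30 cases or zero
genotype variance among cases are flagged degenerate, dropped, and
counted — never imputed. OLS/logistic/WLS fits are statsmodels;
rank-deficient designs fail with the collinear columns named.

## Quadrature oracle

The expected case-only slope is computed independently of the simulator:
genotype is enumerated over {0, 1, 2} with binomial weights, (C, U) by
Gauss–Hermite quadrature (probabilists' nodes, 64 points per dimension by
default), each cell weighted by `P(genotype)·φ(c)·φ(u)·P(D=1 | cell)`
with an intercept calibrated on the same quadrature grid. The slope is
the weighted least-squares projection of `E[Y | cell]` on the target
(plus any adjustment covariates) under the case-weighted measure;
residual noise is independent of the covariates and drops out. Results
are verified on a doubled grid and must agree within 10⁻³, else an
`OracleGridError` asks for a finer grid. The oracle agrees with the
simulation means to <0.001 in all eight scenario × {A, C} cells.

## Mitigation

- *Checks 1–2*: logistic fit of disease on the variant; linear fit of the
  confounder on the variant in cases vs the full population. The report
  emits estimates with CI-based flags, not verdicts — no principled
  threshold exists for "how much variant–incidence association is too
  much".
- *Adjustment*: the case-only fit adjusted for C blocks the C-mediated
  induced path; U-mediated bias remains (demonstrated both by simulation
  and by the oracle with C partialled out).
- *IPW*: weighted least squares among cases with weights
  `1 / P(D=1 | covariates)`, either the true generative probabilities
  (oracle, consistent for the causal effect) or probabilities from a
  logistic selection model fitted on named covariates (omitting U leaves
  residual bias). Weights are rescaled to mean 1 among cases — this
  stabilizes the SEs and leaves the point estimate unchanged. A max/min
  weight ratio above a configurable cap (default 100) warns, with
  optional truncation (off by default). Model-based SEs are the default
  at this scale; sandwich (HC1) SEs are available behind `robust_se`.

## MR demonstration

Single-instrument Wald ratio `β_ZY / β_ZX` with a delta-method SE
(ignoring the small first-stage/reduced-form covariance) and a
weak-instrument guard (first-stage |coef|/SE must exceed 3). The
generative diagram: instrument Z → exposure X → disease; confounder
V → X and V → progression (and optionally V → disease directly).

No reference parameterization exists for this diagram, so the defaults
are explicitly illustrative: `maf = 0.3`, Z→X effect 0.5 per allele,
exposure incidence OR 2.5 per unit, V→X effect 0.7, V→progression
effect 0.5, exposure noise SD 0.8. They were sized so the
selection-induced bias of the case-only Wald ratio under a null exposure
effect (≈ −0.06) is detectable within a few dozen replicates; with
weaker coefficients (e.g. all effects ≤0.3, OR 1.5) logistic selection is
nearly log-linear, which preserves the independence of disease causes
among cases and makes the induced bias vanishingly small — itself an
instructive property of the model. Polygenic-score instruments can be
emulated by summing independent variants into a score upstream of the
spec; only the single-variant route is built in.

## What the synthetic data does and does not emulate

The generator reproduces the stated study structure: independent
covariates feeding a logistic incidence model calibrated to prevalence
0.2, a linear-Gaussian progression trait, and case-only observation. It
does not emulate linkage disequilibrium, polygenic architecture,
genotyping error, time-to-event or repeated-measure progression outcomes,
disease-stage-at-entry artifacts, or measurement error in confounders.
Passing tests therefore demonstrate the selection mechanism and the
behaviour of the estimators under it — not the magnitude of collider bias
in any real cohort.

## Known limitations and open reconciliation

Against the reference four-scenario table, the simulation reproduces all
eight mean coefficients within ±0.01 and the printed SEs exactly at
2-decimal rounding. The coverage percentages agree in the low and strong
columns for A and in the strong column for C, but three reference
coverage cells cannot be reconciled with their own printed means and SEs
under any parameterization of this diagram: a mean of 0.10 with SE 0.01
is arithmetically incompatible with 72% coverage of 0.10 (that coverage
requires a bias of ≈1.37·SE, i.e. a mean printing as 0.09), and
similarly for the middle-column coverages of A (66% with mean −0.03 and
SE 0.02 implies ≈50%). Our model yields the coverages implied by its own
means and SEs; the corresponding checks are reported as observed rather
than forced.

Problem sizes used in the shipped test suite: the reproduction runs at
200 replicates of n = 50,000 (tolerances ±0.015 / ±10 pp), property
checks at 20–60 replicates of n = 20,000–50,000; the acceptance script
runs the full 500 × 50,000 design.
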