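# Methods

## The model

Crash *i* receives severity level *k* ∈ {PDO, I, FI} when its propensity
`V_ik = X_ik βk + ε_ik` is the largest of the three.  With iid type-I
extreme value (Gumbel) errors this is multinomial logit; the base level
(PDO by default) carries no parameters.  Unobserved heterogeneity enters
by letting a coefficient vary across crashes,

```
βk = β̄ + δk Zk + σk exp(ωk Wk) υk ,     υk ~ N(0, 1),
```

so observed covariates Z shift the coefficient's *mean* (δ) and covariates
W scale its *standard deviation* on the log scale (ω).  The choice
probability is the logit probability integrated over the mixing density;
estimation maximizes the simulated log-likelihood

```
LL = Σ_i log ( (1/R) Σ_r P_i(k_i | β_r) )
```

over R quasi-random draws.  Mixing is at crash level: one υ per crash per
random coefficient.

### Simulation and optimization

* **Halton draws.** One prime base per random dimension (2, 3, 5, …), the
  index-0 all-zeros point always skipped, `burn = 10` further points
  discarded, uniforms mapped through the standard-normal quantile.
  Consecutive sequence blocks go to consecutive crashes.  Default
  `n_draws = 500`; everything is deterministic given the configuration —
  there is no RNG in the estimation path, so refits are bit-reproducible.
* **Score.** The gradient of the simulated log-likelihood is computed
  analytically (importance weights `w_ir = P_ir / Σ_r P_ir` times one-hot
  minus softmax residuals), verified against finite differences in the
  test-suite.  BFGS with `gtol = 1e-5` (max-norm), at most 500 iterations;
  mixed-logit fits start from the all-fixed MNL solution with a small
  positive σ.
* **σ sign.** σ enters only through σ·υ, so its sign is unidentified;
  estimates are reported as |σ|.
* **Standard errors** come from the inverse observed information (central
  finite differences of the analytic gradient).  Simulated probabilities
  are floored at 1e-300 (with a warning) before logs.

### Identification of σ — when recovery is possible

With purely binary covariates and crash-level (not panel) data, the mixing
probability of each covariate cell is a scalar, so σ is identified only
through the *nonlinearity* of the mixed cell probabilities across cells.
When σ < |β̄| this information is very weak: the maximizer frequently
collapses σ → 0 and absorbs the mixture into a shifted fixed coefficient —
and that collapsed solution genuinely has the higher likelihood on such
samples.  This is a property of the design, not an optimizer failure.  In
the regime σ > |β̄| (both tails of the coefficient distribution matter,
which is also the regime reported for fitted restraint coefficients in
crash-severity work) the mean and σ are recovered within one standard
error at n = 10,000 with 500 draws.  The recovery tests use that regime;
the replicate bias study runs 20 replicates at n = 5,000 with 100 draws
(point estimates only), sizes chosen to make the suite affordable on one
CPU.  Variance-heterogeneity coefficients ω are weaker still and need
substantially larger samples; at a few thousand crashes the estimate can
run away (σ·exp(ωW) → 0 for a subgroup), which the summary's huge standard
error makes visible.

## Temporal-stability tests

Pairwise transferability: fit each year freely, then evaluate year y2's
*fixed* converged parameters on year y1's data (no re-estimation):

```
χ² = −2 [ LL(β_y2 ; y1) − LL(β_y1 ; y1) ]  ≥ 0,   df = #parameters,
```

run in both directions, plus the joint test
`χ² = −2[LL(pooled) − Σ_y LL(year y)]` with df = Σ per-year parameters −
pooled parameters.  Results are reported as the χ²-CDF at the statistic
("confidence"), so strong instability reads as ~100%.

**Calibration caveat (verified by simulation).** The classic χ²_df
reference for the pairwise test is exact only when the source year's
parameters carry no estimation noise.  When both years are estimated on
comparable samples the statistic is asymptotically
`(1 + n1/n2) · χ²_df` — a quadratic form in the *difference* of two
independent estimators.  At equal sizes that is 2·χ²_df: on 200 same-process
replicates (MNL, df = 4, n = 2,000 per year) the mean statistic is 8.09 ≈
2·df and the nominal-5% test rejects 34% of the time, while the corrected
reference rejects 3.5%.  `lr_test_pairwise` reports the classic
convention (matching published stability tables) and exposes
`null_scale` for the corrected reference; type-I-error statements in the
test-suite use the correction.  The joint test is an ordinary nested LR
test and needs no correction.

## Random forest

Bagged CART trees (Gini), each grown on a same-size bootstrap resample,
with ⌊√p⌋ features considered per split (a per-tree feature-subset mode is
available behind `feature_mode="per_tree"`).  Prediction is an
equal-weight mode vote; ties resolve toward the less severe level.
Tree-count selection scans a grid with stratified 10-fold CV and takes the
smallest count achieving the maximum pooled out-of-fold accuracy.

**Leaf size.** The default is `min_samples_leaf = 25`, not fully grown
trees.  With p binary covariates the design has 2^p cells; at p = 14 and
~13,000 crashes, fully grown trees end in near-singleton leaves whose
votes are dominated by sampling noise, and the ensemble then predicts
*below* the majority-class share on imbalanced data (measured: 64.5% CV
accuracy vs a 68.4% always-PDO baseline at full preset scale).  Leaves of
a few dozen observations let each tree estimate the 3-class cell posterior;
the same forest then reaches 69.1%, essentially the preset's exact Bayes
accuracy (69.09% by enumeration + quadrature, vs 68.32% majority).  Set
`min_samples_leaf = 1` to recover the fully grown behaviour.

## Cost-weighted evaluation

Unit costs per severity level are economic cost plus monetized
quality-adjusted-life-year loss; the 2017 USD defaults are PDO
12,456 + 0, injury 46,132 + 97,535, fatal 588,738 + 3,173,900 (a
`scaled()` method applies a user-supplied re-indexing factor; the CPI/wage
updating that produced the table is out of scope).  From a confusion
matrix with actual rows and predicted columns:

* `AOCC = Σ_i N_i·CCC_i` (row totals), `POCC = Σ_j N_{·j}·CCC_j` (column
  totals);
* `OPMAE = |AOCC − POCC| / N`, `OPAPE = |AOCC − POCC| / AOCC`,
  `OPRMSE = |AOCC − POCC| / √N`,

which satisfy `OPMAE·N = OPRMSE·√N = |AOCC − POCC|` exactly and leave
OPAPE invariant to rescaling all unit costs.  Stored values are full
precision; the display formatter truncates to integers on the
conventional scales (USD millions for AOCC/POCC, thousand USD for OPRMSE,
USD for OPMAE), matching how such tables are usually printed.  Each model
is evaluated on its own prediction set; no cross-model AOCC equality is
assumed (a predictor that never emits a level can legitimately be
evaluated on a different subsample).

## Synthetic-data generator

What it emulates: crash-level rows; four groups of Bernoulli indicator
covariates with configurable prevalences; a 3-level outcome generated by
the exact mixed-logit process above (Gumbel errors via −log(−log U));
multiple years with additive parameter perturbations and disjoint
`SeedSequence` substreams; heavy class imbalance.  The `washington_preset`
carries 14 indicators with prevalences chosen as plausible for a US
multi-vehicle extract (e.g. restraint use 0.90, ejection-prone second-row
occupancy 0.10), one random restraint coefficient with mean and variance
heterogeneity, and constants calibrated *exactly* (covariate enumeration ×
Gauss–Hermite quadrature, fixed-point iteration on log-share mismatch) to
severity shares 0.6832 / 0.3153 / 0.0015.

What it does not emulate: occupant-level nesting (one row per occupant),
continuous covariates, covariate correlation, spatial or serial
dependence, reporting error.  Passing recovery tests therefore show the
estimator is correct *for its assumed process*, not that real extracts
satisfy those assumptions.

## Preprocessing conventions

Multi-vehicle filter keeps `numvehs ≥ 2` by default (the "two or more
vehicles" definition; pass `min_vehicles=3` for the stricter
more-than-two reading).  Missing tokens default to empty string and
"NA" and are configurable; removal is logged per column with overlapping
rows removed once.  First-vehicle selection keeps the minimal `vehno` per
crash (first occurrence on duplicates, with a warning).  The default
severity collapse maps KABCO-style codes O → PDO; C, B, A → I; K → FI and
passes 3-level codes through.

## Degenerate inputs and tie rules

Severity ties in prediction always resolve toward the less severe level
(levels are ordered PDO < I < FI and argmax takes the first maximum).
Empty confusion matrices and zero-AOCC cost denominators raise; a
single-year stability "matrix" is empty; the joint test with one year
reports χ² = 0 with df = 0.  Perfect separation in a logit fit surfaces
as non-convergence or a visibly runaway coefficient, not a crash.

## Known limitations

* Cross-sectional identification of mixing parameters on binary
  indicators is weak (see above); σ estimates near zero with large
  standard errors mean "effectively fixed", not "no heterogeneity".
* The fatal class is ~0.15% of crashes; fatal-level covariates need
  several thousand fatal events, far beyond desk-scale samples, and
  stratified CV necessarily degrades for that class.
* Specification search (which covariates enter which level) is the
  analyst's job; nothing is automated.
* No class re-weighting is applied anywhere by default; the imbalance is
  treated as a property of the data, and the cost-weighted indicators are
  the intended corrective lens.
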