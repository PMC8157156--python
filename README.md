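# crashsev

Injury-severity analysis for multi-vehicle road crashes: who gets hurt,
which crash characteristics drive it, and how well competing predictors do
when errors are priced in dollars rather than counted.

Police-reported crash data give each crash a three-level outcome —
property damage only (PDO), injury (I), fatal injury (FI) — plus binary
indicators in four groups (driver, roadway, crash, occupant
characteristics).  `crashsev` implements the full analysis pipeline for
such data, exercised end-to-end on synthetic crashes with known ground
truth:

* **Synthetic data** (`crashsev.datasets`) — crashes drawn from the exact
  process the estimators assume: severity propensities
  `V_k = X βk + ε_k` with iid Gumbel errors, Bernoulli indicator
  covariates, and normally mixed coefficients
  `βk = β̄ + δk Zk + σk exp(ωk Wk) υk`, `υ ~ N(0,1)`.  A preset emulates a
  two-year Washington State multi-vehicle extract (~13,000 crashes,
  68.3% / 31.5% / 0.15% severity shares), with constants calibrated
  exactly by covariate enumeration + Gauss–Hermite quadrature.
* **Preprocessing** (`crashsev.preprocess`) — raw vehicle-level extracts to
  one analysis row per crash: multi-vehicle filter (`numvehs`),
  completeness screen, first-vehicle deduplication (`vehno`), KABCO → 3-level
  severity collapse.
* **Mixed logit** (`crashsev.mixedlogit`) — multinomial logit and
  random-parameters logit with heterogeneity in means and variances,
  estimated by simulated maximum likelihood over Halton draws (default
  500, burn 10) with an analytic simulated score; standard errors from the
  inverse observed information; distributional shares `Φ(−β̄/σ)`.
* **Temporal stability** (`crashsev.stability`) — pairwise transferability
  tests `χ² = −2[LL(β_y2; y1) − LL(β_y1; y1)]` and the joint
  pooled-versus-separate test, reported as χ²-CDF "confidence levels" in
  the field's `chi2 (df)[confidence%]` convention.
* **Random forest** (`crashsev.forest`) — bagged trees with sqrt-feature
  subsetting, equal-weight mode voting (ties toward the less severe
  level), learning-curve tree-count tuning, stratified 10-fold CV.
* **Cost evaluation** (`crashsev.evaluation`) — confusion matrices and the
  comprehensive-crash-cost framework: per-level unit costs
  `CCC_i = ECC_i + QALYCC_i` (2017 USD defaults: PDO 12,456; injury
  143,667; fatal 3,762,638), actual and predicted overall costs
  `AOCC = Σ_i N_i·CCC_i`, `POCC = Σ_j N_{·j}·CCC_j`, and the error
  indicators `OPMAE = |AOCC−POCC|/N`, `OPAPE = |AOCC−POCC|/AOCC`,
  `OPRMSE = |AOCC−POCC|/√N`.

## Worked example

Price two predictors' confusion matrices (a mixed logit and a random
forest evaluated on a two-year Washington multi-vehicle sample) with the
2017 unit costs:

```sh
python examples/05_crash_cost_evaluation.py
```

```
display-scale comparison (costs truncated to integers):
                      mixed-logit random-forest
R_overall (%)                56.6         67.11
OPMAE (USD)                  2143         14076
OPAPE (%)                    3.61         27.12
OPRMSE (thousand USD)         137           895
POCC (USD millions)           252           153
AOCC (USD millions)           243           209
```

The forest is more accurate crash-by-crash (67% vs 57%), but it never
predicts a fatal crash, so it misprices the total crash cost by 27%
(POCC 153M vs AOCC 210M USD) where the mixed logit is off by only 3.6% —
cost-weighted evaluation reverses the model ranking.  Similarly,

```python
>>> from crashsev import share_negative
>>> share_negative(-1.5017, 4.5840)
0.6284
```

reads a fitted N(−1.5017, 4.5840²) restraint coefficient as "negative for
62.84% of crashes": restraint use lowers injury odds for most crashes, not
all.

## Scope notes

The synthetic preset emulates the *structure* of a HSIS-style extract, not
any particular state's coefficient estimates; raw extracts are ingested
via `crashsev.preprocess` when available.  See `docs/methods.md` for the
model, identification caveats (when a mixing σ is and is not estimable),
the calibration of the temporal-stability test, and all numerical choices.
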