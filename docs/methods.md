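# Methods

## Model and assumptions

The package addresses development-time *case-mix shift*: the predictor
distribution differs between the pre-shift (source, R = 1) and post-shift
(target, R = 0) portions of the development data,

    P(X | R = 1) ≠ P(X | R = 0),    P(Y | X, R = 1) = P(Y | X, R = 0),

and the target portion is assumed to represent the deployment population.
Everything downstream relies on these two assumptions plus positivity where
source data are meant to contribute: a source region with no target
counterpart receives propensities near 1 and weights near 0 — the method
deliberately refuses to extrapolate.

**Membership model.** PS_i = P(R = 1 | X_i) is estimated by binary logistic
regression of R on the predictors (by default the same set used in the
prediction model). Unpenalized maximum likelihood is the default. Under a
complete shift the classes are separated and the MLE diverges; the optimizer
(L-BFGS, maxiter 1000) then returns boundary propensities, which is the
behaviour the weighting needs (all source weights ≈ 0), and a
`QuasiSeparationWarning` tells the user this happened. An optional ridge
penalty (`ridge > 0`, implemented as an L2-penalized logistic fit with
C = 1/ridge, intercept unpenalized) is available when separation is an
artefact rather than the design. Propensities are clipped to
[1e-12, 1 − 1e-12] before odds are formed so the raw regime cannot divide by
zero.

**Weights.** Source rows get w = ((1 − PS)/PS)·(s/n); target rows w = 1.
Regimes: `raw` (no limit; the baseline importance-weighting comparator),
`capped` (w ← min(w, 1)), `scaled` (all source weights multiplied by
c = s/Σw only when Σw > s, so the source effective sample size never exceeds
the actual source size; otherwise the raw weights pass through and no factor
is recorded). Effective sample size is the plain sum of weights — not the
Kish formula — so that an unweighted model's ESS equals its row count and
the regimes are comparable on one scale.

**Weighted fit.** The prediction model maximizes
LL = Σ w_i [y_i log p_i + (1 − y_i) log(1 − p_i)] via IRLS
(statsmodels GLM with binomial family and `var_weights`; tolerance 1e-8,
maxiter 100, non-convergence raises rather than returning a partial fit).
Zero-weight rows are removed beforehand — they contribute nothing to the
likelihood but would otherwise pollute the reported log-likelihood. Weights
are treated as fixed constants: no sandwich correction is applied, because
the capping/scaling regimes are the mechanism that controls standard-error
optimism. Three strategies wrap this fit: `all_unweighted`, `target_only`,
and `membership_weighted`; the all-data strategies may add the membership
dummy R to absorb an event-rate shift, and predictions set the dummy to 0
(the target level) by default since deployment is in the target population.

**Metrics.** CITL is the intercept of a logistic model with the linear
predictor as offset; the calibration slope is the coefficient of the linear
predictor as sole covariate; both are fitted by IRLS. The C-statistic uses
the standard half-credit tie convention; AUC-PR is the non-interpolated
step-curve area (ties grouped), which is exactly reproducible by threshold
enumeration; the Brier score is the mean squared error. All metrics are
evaluated on target rows only.

**Bootstrap optimism.** B replicates (default 200) are drawn with
replacement, stratified by R so s and n — and hence the s/n factor in the
weights — are preserved. The membership model and weights are re-estimated
inside every replicate, so the reported optimism includes weight-estimation
uncertainty; the replicate-model test performance is measured on the
original full target set. The adjusted metric is apparent − mean(apparent_b
− test_b). Replicates whose target rows carry a single outcome class are
discarded and redrawn; more discards than B aborts the run. Stratification
and per-replicate re-weighting are design choices of this package: the
alternative (freezing the weights) understates uncertainty.

## Synthetic-data generator

The generator emulates an acute-coronary-syndrome registry cohort: age
(truncated normal, mean 67, SD 12, range 18–103, recorded in whole years as
a registry would), male sex (70%), BMI (27 ± 4.5), diabetes (22%), eGFR
(75 ± 20), reduced LVEF (25%), atrial fibrillation (10%). The outcome
follows one shared conditional model in both strata,

    logit P(Y=1 | X, R) = γ₀ + Σ γ_k x_k + 0.001·(age − 67)² + δ·R,

with per-unit coefficients (age 0.05/y, sex 0.30, BMI −0.02, diabetes 0.40,
eGFR −0.015, reduced LVEF 0.90, AF 0.50) chosen to give a C-statistic near
0.75. The mild quadratic age term is shared by both strata — the case-mix
invariance of P(Y | X, R) holds exactly — but makes the *fitted* linear
model realistically misspecified, as any linear CPM is on real data. This
matters: with an exactly linear truth every strategy's MLE is consistent
regardless of case-mix, and the region-dependent bias the weighting corrects
could not exist. Curvature can be disabled (`curvature={}`) for experiments
that need a correctly specified model. δ adds an event-rate shift to the
source stratum only. The intercept γ₀ is calibrated by root-finding so the
*target*-stratum event rate hits a requested prevalence (calibration draw of
200,000 rows, fixed internal seed, so presets are reproducible).

Case-mix shift is imposed by truncating the shift variable's distribution to
stratum-specific ranges: complete (source ages 76–103 vs target 18–75 —
disjoint because ages are integer years), partial (18–80 vs 57–103), or none.
Preset scenarios mirror the six tabulated designs — complete/partial shift
with low/high target, and two no-shift designs with insufficient target —
at a default scale factor of 0.1 on the full source/target sizes and a
default 2% prevalence; the original 0.21% rare-outcome setting is available
(`prevalence=0.0021, scale=1.0`) but slope estimation at reduced scale is
unstable with only a handful of events, hence the raised default for
desk-scale work.

What the generator does *not* emulate: missing data (real registries need
imputation; synthetic cohorts are complete), correlation between predictors
(drawn independently within stratum), shifts in more than one variable at a
time, and outcome-model drift. Passing tests therefore demonstrate the
method's behaviour under clean, single-variable case-mix shift — not
robustness to the full messiness of registry data.

## Minimum sample size

The Riley-criteria calculator returns the maximum of: (1) the shrinkage
criterion n₁ = P / ((S−1)·ln(1 − R²/S)); (2) the small apparent-R²-optimism
criterion, the same formula at S₂ = R²/(R² + δ·max R²) with margin δ = 0.05;
(3) the prevalence-precision criterion n₃ = (1.96/δ)²·φ(1−φ), margin 0.05
absolute — each rounded up, with max R² = 1 − (φ^φ(1−φ)^(1−φ))². The margins
follow the published defaults; the breakdown is always reported so the
binding criterion is auditable.

When only an anticipated C-statistic is available, the Cox–Snell R² is
obtained by simulating 10⁶ observations with exactly φ·10⁶ events, linear
predictor N(μ, 1) among events and N(0, 1) among non-events with
μ = √2·Φ⁻¹(C) (so the implied concordance equals C), then fitting a
logistic regression of outcome on linear predictor and taking
R² = 1 − exp(−(2/N)(LL_model − LL_null)). The normal quantiles are drawn by
*systematic* (stratified) sampling with a seeded uniform shift rather than
independent draws: at φ ≈ 0.002 only ~2,000 events inform the fit and
independent sampling leaves ~5% seed-to-seed noise in the resulting minimum
n, whereas systematic sampling pins the estimate to its large-sample value
to under 0.5% for any seed. This is a variance-reduction choice, not a
change of estimand.

## Numerical choices and degenerate inputs

- Split rules use closed intervals; a cutoff split puts "above" strictly
  above the threshold. Rows eligible for both sets go to the target set
  first (the target set is the scarce, defining set in every design);
  subsampling is without replacement and seed-deterministic.
- Cohort CSV round-trips preserve integer-coded columns exactly and
  continuous columns to 12 significant digits.
- Single-class membership or outcome raises a specific error instead of a
  numerical crash; a constant linear predictor makes the calibration slope
  undefined and is rejected.
- All simulation and resampling randomness flows through
  `numpy.random.default_rng(seed)`; every CLI run writes a manifest with its
  configuration and seeds.

## Problem sizes used in the test suite

The heavier checks run at reduced scale chosen as the package's own test
design: the overfitting check uses 50 replicate cohorts (n = 1,000 at 2%
prevalence, ~20 events against a ~4,000-row requirement) with B = 100; the
directional partial-shift comparison uses 100 replicate scenario runs at
s = 9,273 / n = 2,000 with B = 25 per model. B trades Monte-Carlo noise in
each replicate's optimism estimate against runtime; the comparisons average
over replicates, so a moderate B suffices.

## Known limitations

- The method corrects case-mix shift only; predictor–outcome association
  shift is out of scope (the dummy-R adjustment crudely absorbs a pure
  event-rate shift but changes the parameter count).
- The membership model is a main-effects logistic fit; strongly nonlinear
  shifts would need interactions or splines in the membership model.
- Weight-induced variance inflation is controlled, not eliminated; the raw
  regime is provided only as the comparator it is.
- ESS-as-weight-sum overstates the information in unevenly weighted data
  relative to the Kish definition; it is used for comparability, not
  inference.
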