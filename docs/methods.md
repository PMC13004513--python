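# Methods

This document records the statistical definitions, conventions, and
algorithmic choices implemented in survflow, so that every number the package
prints can be traced to a formula. Notation: subject `i` has follow-up time
`tᵢ > 0` and event indicator `δᵢ ∈ {0, 1}` (1 = event observed, 0 =
right-censored); distinct event times are `t₍₁₎ < … < t₍m₎` with `dⱼ` events
and `nⱼ` subjects at risk at `t₍ⱼ₎`.

## Data model and tie convention

`SurvivalDataset` is an immutable record of subject ids, times, events, a
dense covariate matrix, and optional group labels. Times must be positive and
finite; events are coerced from common aliases (`yes/no`, `true/false`,
`dead/alive`, `event/censored`, `1/0`) at read time. Missing time or event
values are an error unless `drop_missing=True`, in which case the dropped row
count is surfaced via a `UserWarning` — silent row loss hides data problems.

When an event and a censoring share the same timestamp, the censored subject
is counted in the risk set at that time (events happen "just before"
censorings). This is the standard convention and is applied consistently by
the KM estimator, the log-rank test, and the Cox partial likelihood.

Stratification (`StratificationRule`) splits on one feature: median and
explicit-cutoff modes use the strictly-below vs at-or-above convention
(`value < cut → low`, `value ≥ cut → high`), so boundary ties land
deterministically in the high group; the sample median for even `n` is the
midpoint of the two central order statistics. Quantile mode assigns ordinal
bins `Q1…Qk`.

## Kaplan–Meier estimator

Product-limit estimate `Ŝ(t) = ∏_{t₍ⱼ₎ ≤ t} (1 − dⱼ/nⱼ)`, a right-continuous
step function. With zero censoring it reduces algebraically to one minus the
empirical CDF (the product telescopes), which the tests verify to machine
precision.

Variance by Greenwood's formula,
`Var[Ŝ(t)] = Ŝ(t)² Σ_{t₍ⱼ₎ ≤ t} dⱼ / (nⱼ(nⱼ − dⱼ))`.

Confidence bands use the complementary log-log transform: with
`θ = log(−log Ŝ)` and `se(θ) = sqrt(Σ dⱼ/(nⱼ(nⱼ−dⱼ))) / |log Ŝ|`, the
`1−α` band is `Ŝ^{exp(±z_{1−α/2} se(θ))}`. Unlike plain (linear) Greenwood
intervals, these bands are guaranteed to stay inside (0, 1) and behave better
near the extremes; this is why cloglog is the default (and only) transform.
Where `Ŝ = 0` the band collapses to [0, 0].

Median survival is the smallest event time with `Ŝ(t) ≤ 0.5`; if the curve
never reaches 0.5 the median is reported as not reached (`None`) rather than
extrapolated. Horizon summaries beyond the last event time return the last
step value flagged as extrapolated.

## Log-rank test (k groups)

At each event time `t₍ⱼ₎`, group `g`'s observed events `d_{gj}` are compared
with the hypergeometric expectation `e_{gj} = dⱼ n_{gj}/nⱼ`. The covariance
of the `(k−1)`-vector of `O − E` sums uses the finite-population correction
`V_{gh,j} = dⱼ (nⱼ − dⱼ)/(nⱼ − 1) · (n_{gj} δ_{gh}/nⱼ − n_{gj} n_{hj}/nⱼ²)`
(terms with `nⱼ = 1` contribute zero). The statistic is
`(O−E)ᵀ V⁻ (O−E)` using the Moore–Penrose pseudo-inverse, with degrees of
freedom equal to `rank(V)` — this handles degenerate configurations (e.g. a
group exhausted early) without failing. P-values come from the χ² upper tail.

For tie-free two-group data the log-rank χ² equals the Cox score test at
`β = 0` with Breslow ties; with ties they differ slightly because the
log-rank variance carries the `(nⱼ−dⱼ)/(nⱼ−1)` correction. The equivalence
is verified on tie-free fixtures in the tests.

Pairwise comparisons run the two-group test on every pair and report
Bonferroni-adjusted p-values `min(p · #pairs, 1)` — conservative but exact
control of the family-wise error rate with no independence assumptions.

## Cox proportional hazards

Model `h(t|x) = h₀(t) exp(βᵀx)`. Covariates are mean-centered internally for
numerical stability; reported coefficients are unaffected and stored means are
used for prediction. The partial likelihood is maximised by Newton–Raphson
from `β = 0` with step-halving (up to 20 halvings whenever a step fails to
increase the log partial likelihood), stopping when `max|Δβ| < 1e-9` or the
relative log-likelihood change is below `1e-12`, with a cap of 100 iterations.
Risk-set sums are computed via reverse cumulative sums over time-sorted
arrays, with a max-shift on the linear predictor to avoid overflow.

Ties: Efron's approximation is the default — within a tied group of `dⱼ`
events the risk-set denominator is progressively down-weighted by
`(r/dⱼ) · (sum over the tied events)` for `r = 0…dⱼ−1` — because it is more
accurate than Breslow's when ties are common and exact when there are none.
Breslow is available for cross-package comparability.

Inference is Wald: `se(β̂) = sqrt(diag(I(β̂)⁻¹))`, hazard ratios
`exp(β̂ ± z se)`. An ill-conditioned information matrix (condition number
above 1e12) raises a collinearity error rather than returning unstable
numbers. Monotone partial likelihoods (perfectly separated covariates) have
no finite maximiser; coefficients exceeding |β| > 20 are reported with
`converged=False` and an explanatory warning instead of a spurious "converged"
answer.

The baseline cumulative hazard is Breslow's estimator
`Ĥ₀(t) = Σ_{t₍ⱼ₎ ≤ t} dⱼ / Σ_{i ∈ R(t₍ⱼ₎)} exp(β̂ᵀ(xᵢ − x̄))`, giving absolute
survival predictions `Ŝ(t|x) = exp(−Ĥ₀(t) exp(β̂ᵀ(x − x̄)))`. Models serialize
to plain JSON dicts and reload exactly.

## Feature screening and multiplicity

`rank_survival_features` fits one univariate Cox model per candidate feature
(a specialised scalar Newton solver sharing the same convergence rules) and
ranks by Wald p-value, breaking ties by larger |z| and then name. Features
that are constant, non-finite, or non-convergent are labelled
(`degenerate` / `non_converged`) and left unranked rather than dropped
silently.

Multiplicity uses Benjamini–Hochberg q-values (step-up: sort p ascending,
`qᵢ = min_{j ≥ i} pⱼ m/j`). BH controls the false discovery rate, which is the
appropriate error rate for screening many candidate biomarkers where a
controlled fraction of false leads is acceptable; Bonferroni (used for the
handful of pairwise log-rank tests) would be needlessly conservative here.

## Risk cohorts

`build_risk_model` fits a multivariable Cox model on the selected features
and uses the linear predictor `β̂ᵀ(x − x̄)` as a risk score. The default
split is at the score median (same <, ≥ convention as stratification),
labelled `low_risk`/`high_risk`; explicit cutoffs and quantile bins are
available. `evaluate_stratification` then reports per-group KM curves and the
log-rank test. The accompanying C-index is labelled "training (optimistic)"
because selection and evaluation reuse the same cohort; honest assessment
requires held-out data, which is out of scope for these pipelines.

## Nomogram

For a fitted model with observed covariate ranges `[aⱼ, bⱼ]`, the reference
value of feature `j` is whichever range end minimises `βⱼ x` (the most
favourable observed value, assigned 0 points). The point scale is
`s = 100 / maxⱼ |βⱼ| (bⱼ − aⱼ)`, so the most influential feature spans exactly
100 points. Feature points are `βⱼ (xⱼ − refⱼ) s ≥ 0`; total points `P` map
back through `η = P/s + βᵀ(ref − x̄)` and the Breslow baseline to survival at
each horizon. This is an exact algebraic reparameterisation — chart readings
reproduce `predict_survival` to machine precision, which the tests assert at
1e-9. Out-of-range patients are scored by linear extrapolation and flagged.

## Concordance index

Harrell's C considers pairs `(i, j)` where the comparison is usable: `tᵢ < tⱼ`
with `δᵢ = 1`, or `tᵢ = tⱼ` with exactly one event (the event-bearing subject
is the earlier member). A pair is concordant when the earlier subject has the
higher risk score; score ties count ½. The implementation enumerates all
O(n²) pairs exactly (in vectorised blocks), rather than using an approximate
or downsampled estimator; zero usable pairs is an error, not a 0/0.

## Simulator

`simulate_ph_dataset` draws covariates (standard normal or Bernoulli), forms
`η = βᵀx`, and inverts the survival function: for a Weibull(k, λ) baseline,
`T = λ (−log U / exp(η))^{1/k}` (exponential is the k = 1 special case).
Censoring times are exponential with rate `c` chosen by bisection so that the
expected censoring fraction `E[1 − exp(−cT)]` matches the requested target,
estimated on a 10,000-draw pilot sample with a seed derived from the config
seed. The realised fraction therefore fluctuates around the target with
sampling noise; the returned `SimulationTruth` records β, the baseline, the
calibrated censoring rate, the realised fraction, and each subject's linear
predictor.

The simulator generates exactly proportional hazards with independent
censoring. It deliberately does not emulate time-varying effects, informative
censoring, competing risks, or covariate correlation structures — it exists
to provide cohorts with known ground truth for validating the estimators, not
to mimic any particular disease.

## Pipelines and determinism

`pipeline_km_compare` (stratify → KM per group → log-rank → Cox on the group
indicator, optionally adjusted) and `pipeline_biomarker_screen` (rank →
select top-k → risk model → cohorts → KM/log-rank → C-index) produce nested
dict reports. Errors are prefixed with the failing stage name. Reports
serialize with sorted keys and fixed separators, so rerunning a pipeline on
identical input yields byte-identical JSON — verified in the tests.

## Validation strategy and limitations

The test suite validates against three kinds of oracle: hand-computed small
fixtures, brute-force reimplementations (exact partial-likelihood grid
search, O(n²) pairwise concordance loops), and independent libraries
(lifelines, scikit-survival) used only as cross-checks. Monte-Carlo
acceptance tests assert distributional properties — confidence-interval
coverage near the nominal 95%, log-rank type-I error near 5% with high power
under a doubled hazard, unbiased Cox coefficient recovery, null C-index near
0.5, and screening FDR control under a global null — with tolerances set from
binomial sampling noise at the chosen replication counts. Replication counts
and cohort sizes (hundreds of replicates, cohorts of 200–1000) were chosen to
keep the full suite fast while leaving the tolerance bands several standard
errors wide.

Known limitations: no time-varying covariates or coefficients, no stratified
or penalised Cox, no competing-risks estimators, no proportional-hazards
diagnostics (e.g. Schoenfeld residuals), and the pipelines evaluate on
training data only.
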