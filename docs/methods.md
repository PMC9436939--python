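# Methods

## The model

`mvgee` fits population-average (marginal) regression models to several
longitudinal outcomes at once. The k outcomes measured on subject i at
visit t are stacked into a single response vector, and a response-type
indicator `rtype` (0 for the first outcome, 1 for the second, ...) is
interacted with selected regression terms. For two Gaussian outcomes with
identity link the stacked mean model is

    E[Y | X] = β₀ + β₁·time + β₂·X₁ + β₃·X₂
             + β₄·rtype + β₅·(time × rtype) + β₆·(X₁ × rtype) + β₇·(X₂ × rtype)

so the first outcome's effects are the base coefficients (β₀…β₃) and the
second outcome's are base + interaction (β₀+β₄, β₁+β₅, ...). Dropping an
interaction forces the corresponding effect to be **shared**: one
coefficient applies to both outcomes. That is the point of the joint
model — when an exposure genuinely affects both outcomes equally,
estimating one coefficient instead of two removes a redundant parameter
and (weakly) tightens its standard error.

Estimation is by generalized estimating equations: β solves
Σᵢ Dᵢᵀ Vᵢ⁻¹ (yᵢ − μᵢ) = 0 with Vᵢ = φ·Rᵢ(α) a working covariance over
subject i's **entire** stacked vector (all visits × all outcomes).
Reported standard errors come from the robust sandwich
B⁻¹MB⁻¹ (B = ΣDᵢᵀVᵢ⁻¹Dᵢ, M = ΣDᵢᵀVᵢ⁻¹eᵢeᵢᵀVᵢ⁻¹Dᵢ), which remains valid
when the working correlation is wrong; GEE point estimates are consistent
regardless. A naive (model-based) covariance φ·B⁻¹ is also reported.

## Working correlation structures

Rows of a subject are ordered time-major, response-minor; this ordering
is part of the format contract because it fixes what the structured
correlations mean.

* **independence** — R = I; with identity link this is exactly OLS on the
  stacked data.
* **exchangeable** (primary) — a single α for every within-subject pair,
  serial and cross-response alike; solved via the Sherman–Morrison closed
  form. Moment estimator
  α̂ = Σᵢ Σ_{j<l} e_{ij}e_{il} / (φ̂·(Σᵢ mᵢ(mᵢ−1)/2 − p)), with
  φ̂ = Pearson χ²/(n−p); p is subtracted in both denominators. Estimates
  outside the positive-definite range (−1/(m_max−1), 1) are clamped with
  a warning.
* **ar1** — correlation α^d with d the visit-index separation. Same-visit
  rows of different outcomes would have d = 0, which would force
  correlation 1, so they are assigned d = 1 (documented quirk; AR-1 is
  provided for model-comparison only, exchangeable is the supported
  primary structure). α̂ is the moment estimator over effective-lag-1
  pairs.
* **unstructured** — full moment-estimated correlation matrix; requires
  balanced clusters (identical visit/response patterns) and raises
  otherwise. A non-positive-definite estimate is shrunk toward the
  identity with a warning.

Iteration alternates an exact Fisher-scoring solve of β (exact because
the link is the identity) with re-estimation of φ and the correlation
parameters; convergence is a maximum relative coefficient change below
1e−8 (default), capped at 100 iterations. Non-convergence returns a
result flagged `converged=False` with diagnostics rather than raising.
Clusters of size one contribute independence-like terms; if *no* cluster
has two observations the correlation parameter is pinned at 0 (the fit
then equals independence, which is the only identifiable model).

### One scale, two measurement scales

The stacked model uses a single dispersion φ across outcomes. When the
outcomes' residual scales differ strongly (FBS ≈ 55 mg/dl vs HbA1c ≈ 1 %),
the pooled-residual moment estimate of the exchangeable α is attenuated:
with equal visit counts the estimate converges to
α·(σ₁² + σ₂²·r + 2σ₁σ₂·c) / (σ₁² + σ₂²) for suitable pair-count weights,
about 0.25 for a generating α = 0.5 at the study's scales. This is an
algebraic property of any single-scale stacked GEE, not an estimator
defect; it leaves coefficients consistent and sandwich SEs valid, because
the exchangeable matrix is only a *working* structure. Users who want α̂
to be interpretable should standardize outcomes to a common scale first.
Per-outcome scales (a Kronecker/seemingly-unrelated structure) are out of
scope.

## QIC and structure selection

Model comparison uses the quasi-likelihood under the independence model
criterion, QIC = −2·QL + 2·trace(Ω̂_I·V̂_R), with QL = −Σ(y−μ̂)²/(2φ̂),
Ω̂_I = XᵀX/φ̂ the independence information at the fitted β, and V̂_R the
robust covariance. Under a correctly specified independence model the
penalty tends to 2p. Structure selection is **univariate**: each outcome
is fitted separately under every candidate structure and per-outcome QICs
are summed; the minimum wins, ties going to the structure with fewer
correlation parameters. Candidates that fail or do not converge are
reported and excluded, never silently ranked.

Two caveats discovered while validating, both inherent to QIC:

1. On perfectly balanced panels whose covariates are baseline-only and
   whose time grid is common to all subjects, the exchangeable GLS
   estimate coincides exactly with OLS (Kruskal's theorem), so
   exchangeable and independence tie in QIC to the last bit. Real
   follow-up data are unbalanced (dropout), which breaks the tie in
   favour of the true structure; the packaged selection study therefore
   simulates the cohort-like regime with monotone dropout.
2. QIC charges nothing for correlation parameters, so on balanced data an
   unstructured matrix (91 free parameters at 14 occasions) overfits the
   in-sample residual correlation, deflates the sandwich and wins almost
   surely. On unbalanced data unstructured is not estimable and is
   excluded by the selection contract.

## The three-step procedure

1. **Step I** — fit the full model: every term (intercept, time, each
   covariate) interacted with `rtype`.
2. **Step II** — robust Wald test each interaction; remove **all**
   interactions with p ≥ α (default 0.05) in one simultaneous pass, not
   backward-stepwise. Intercept and time interactions are eligible like
   any other; main effects always stay.
3. **Step III** — refit; the report lists response-specific rows for
   retained interactions and a single shared row (repeated per response
   for readability) otherwise.

p-values are two-sided by default, 2(1−Φ(|z|)); a one-sided reporting
mode (1−Φ(|z|)) is available because published tables of this procedure
are sometimes consistent with one-sided tails. No multiple-testing
correction is applied across the interaction tests — mirroring common
practice for this procedure — and that is deliberately left to the user.

## The synthetic cohort generator

Because the motivating cohort data are not public, the package carries a
generator whose defaults emulate that study's structure: N = 500 type-2
diabetes patients, visits every 3 months from 0 to 39 (14 occasions), two
Gaussian biomarkers — fasting blood sugar (mg/dl) and HbA1c (%) — with
linearly declining means, eleven baseline covariates with the cohort's
prevalences/moments (41.4% male, 64.5% family history of diabetes, 70.4%
hypertension, 61.7% high cholesterol, 19.8% smokers, 14.6% insulin
therapy; age 45.7 ± 8.9 y, disease duration 3.7 ± 2.7 y, weight
78.0 ± 12.6 kg, systolic 138.8 ± 17.6 and diastolic 80.3 ± 7.7 mmHg).

The within-subject stacked residual vector is multivariate normal with a
single exchangeable α (default 0.5) over all pairs, optionally overridden
by a distinct same-time cross-response correlation ρ; positive
definiteness of the implied matrix is checked at construction and
violations raise (no silent repair). Dropout is monotone and MCAR with a
per-visit probability, so GEE consistency holds and recovery tests stay
honest. Identical configurations (including seed) give byte-identical
panels.

Two packaged regimes:

* `recovery_config()` — ground truth for estimator validation: the
  final-model coefficient table verbatim for both outcomes (e.g. time
  slopes −3.05 mg/dl and −0.15 % per month; sex, age, cholesterol history
  and weight truly shared), residual SDs 55 / 1.0, α = 0.5, no dropout
  unless requested.
* `paper_regime_config()` — the demo cohort, built to reproduce the
  observed *descriptive* pattern of the study data: FBS coefficients from
  the final-model table; HbA1c covariate effects scaled by the clinical
  ≈30 mg/dl-per-1% FBS↔HbA1c conversion (using the published HbA1c
  column verbatim would imply a marginal HbA1c SD near 3.9%, three times
  the observed ≈1.0%, and would cap the achievable FBS–HbA1c correlation
  near 0.23); residual SDs 52 / 0.9, α = 0.5, ρ = 0.66, 2% per-visit
  dropout. Analytically this yields per-visit marginal SDs ≈55 mg/dl and
  ≈1.07% and per-visit cross-correlations ≈0.70, inside the observed
  0.61–0.76 band, with monotonically declining mean trajectories.

What the generator does **not** emulate: time-varying covariates,
informative (MNAR) dropout, non-Gaussian outcomes, skewness or floor
effects in biomarker distributions, correlated baseline covariates, and
measurement-occasion jitter. Passing tests therefore demonstrate the
estimator's behaviour under its stated assumptions, not robustness to
those violations.

## Validation studies and problem sizes

`mvgee.validation` (driven by `scripts/acceptance.py` and the acceptance
tests) runs, at the study's own scale of 500 subjects and 14 visits:

* bias and 95% robust-CI coverage over 200 replicates (coverage averaged
  across the 20 coefficients of the truth-structured model);
* QIC selection frequency over 100 replicates in the dropout regime;
* pruning operating characteristics over 1000 replicates — removal rate
  of the four truly-null interactions vs the nominal 95%, and retention
  of interactions whose true effect exceeds 4 robust SEs;
* the shared-vs-specific SE comparison over the same 200 replicates;
* demo-cohort descriptive fidelity (per-visit correlations and trends).

These replicate counts keep each study in the tens-of-seconds to
two-minute range on a single CPU while leaving Monte-Carlo error well
below the decision margins.

## Known limitations

Gaussian/identity only; two-level categorical covariates only (users
pre-code dummies); no weighted GEE for MNAR dropout; no small-sample
sandwich corrections (at N = 500 clusters the plain sandwich is
adequate — observed coverage ≈0.94); no Kronecker-structured working
correlations; AR-1's same-visit convention is a pragmatic quirk, not a
model of simultaneous measurements.
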