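# Methods

This note documents the statistical procedures, default parameters, numerical
choices and limitations of `dataplan`. It is the package's own account of its
science; every number quoted here is computed by the code or its test suite.

## Data model

One participant's record is a *scheduled grid*: one row per planned survey
occasion (default four per day at 09:00/13:00/17:00/21:00 for 30 days), one
column per symptom item, values on the 0–100 visual-analog scale, `NaN` for
missed responses. Missed occasions stay in the grid so that "consecutive"
remains well defined: the dynamic model's lag is one *observation* (nominally
about six hours), and lag pairs spanning a missed occasion are dropped rather
than bridged. Analyses use listwise deletion: only fully answered occasions
enter the correlation matrix and the factor-score series. This is the simplest
defensible treatment of item-level missingness; imputation is out of scope.

## Person-specific factor analysis

Extraction is maximum likelihood on the Pearson correlation matrix of
completed occasions, using the concentrated-likelihood formulation: the ML
discrepancy is minimized over the item uniquenesses ψ (L-BFGS-B on log ψ,
bounds ψ ∈ [0.005, 1] to stop Heywood collapse), with the loadings available
in closed form from the top-k eigenpairs of `diag(ψ)^-1/2 R diag(ψ)^-1/2`.
Rotation is oblimin (γ = 0) by oblique gradient projection, started from the
identity; oblique rotation is the default because the downstream lag-1 model
explicitly assumes correlated factors. Factors are sign-fixed (column sums
positive) and ordered by explained variance. Pattern coefficients can
legitimately overshoot |1| slightly under oblique rotation; the reported
solution clips them to the standardized [−1, 1] contract (the unclipped matrix
stays on the results object).

Number of factors: if not given, Horn's parallel analysis on the participant's
correlation matrix (50 random datasets, 95th-percentile rule, at least one
factor). This is a reproducible, standard default; an explicit `n_factors`
always overrides it.

Per-factor variance share is `Σ_i λ²_{i,f} / n_items` over the full (unmasked)
pattern matrix. Loadings below the salience threshold (default 0.30,
configurable) are reported as absent and are the ones that enter item scoring.
User-supplied variance shares are also accepted when reproducing published
solutions, because any common rescaling cancels under the max-normalization of
the scoring chain.

Fit indices: model χ² = (n−1)·F_ML with
`F_ML = ln|Σ̂| − ln|S| + tr(S Σ̂⁻¹) − p`; null model = mutually uncorrelated
items; TLI and CFI from the usual ratio formulas (TLI set to 1 when the model
χ² is 0 or the baseline ratio degenerates); SRMR is the RMS residual
correlation over the lower triangle including the diagonal. Strict cutoffs
CFI ≥ .95, TLI ≥ .95, SRMR ≤ .08 are codified as the default fit bar.
**Caveat**: χ²-based indices assume independent rows; EMA occasions are
serially dependent, so these indices are approximate and a documented warning
is emitted on every fit.

Avoidance items (reassurance seeking, procrastination, avoiding activities)
enter through a two-step comparison: the model is fitted without and with
them, and they are retained only if the total variance share rises *and* the
augmented model still meets the fit cutoffs; otherwise they are recorded as
excluded items.

Factor scores are Thurstone regression scores, `W = R⁻¹ (Λ Φ)`, applied to
z-scored items and re-standardized per factor (population sd 1). Hand-built
solutions without a factor-correlation matrix get loading-weighted composites
instead, so an identity loading matrix passes items through unchanged.

## Lag-1 dynamic factor model

Per-equation OLS of each factor score at *t* on all scores at *t−1*, which for
this saturated VAR(1) gives the same point estimates as a joint fit. Betas are
standardized (slope × sd(x)/sd(y) over the used lag pairs), so in the
one-factor case the coefficient equals the lagged correlation exactly. At
least 30 usable lag pairs are required. Cross-predictions with p ≥ α (default
.05, configurable) are pruned; autoregressions are always retained. All
consecutive completed occasions count as one lag by default; a
`drop_overnight` flag removes pairs spanning different calendar days, since
the overnight gap is roughly twice the nominal within-day spacing.

## Scoring chain and plan rules

The seven-step chain is deterministic algebra (see README for the formulas).
Numerical conventions, chosen where the procedure leaves room:

- The 1/N_factors term in the raw factor score is applied to the dynamic term;
  it is constant across factors and cancels under normalization, which the
  test suite asserts exactly (scale-invariance property).
- Normalization by a zero maximum is defined as zero and raises a
  `DegenerateInputWarning` instead of erroring, so degenerate participants
  surface loudly without breaking batch pipelines.
- A module none of whose matched items survived factor analysis scores 0 on
  all three variants (the item average would otherwise be 0/0) and is
  excluded from the plan, consistent with the zero-exclusion rule.
- Ties in final module scores are broken by ascending module number,
  mirroring the Unified Protocol's canonical sequence without weighting
  content.
- `variance_explained` reports round-half-up integer percent (0.58 → 34);
  internal computation keeps full precision.
- Modules 1 and 8 never enter the equations; they are rule-assigned. The
  Module-1 rule fires on any of: a reminder call was made, completion below
  the 80% threshold (exactly 80% passes — "at least 80%"), or more than 30
  days needed to accumulate the required survey count.

## Synthetic generator

`generate_ema` simulates `η_t = B'η_{t−1} + ζ_t` with the innovation
covariance rescaled (discrete Lyapunov solve) so each factor's stationary
variance is exactly 1 — the generating path matrix is then directly comparable
to estimated standardized betas. The first occasion is drawn from the exact
stationary distribution, so no burn-in is needed. Items are
`y = baseline + item_sd · (Λη + ε)`, clipped to [0, 100]; defaults
(baseline 50, item_sd 10, noise sd 0.5 on the latent scale) keep clipping
inert, which a test asserts. Missingness removes whole occasions completely at
random to a deterministic count; compliance-dependent missingness is not
modeled.

What the generator emulates: the sampling protocol (4 × 30 schedule, 0–100
scale), low-dimensional latent structure with simple-structure loadings,
stationary lag-1 dynamics, occasion-level MCAR missingness. What it does not:
response styles and scale clumping, diurnal cycles, trends and
non-stationarity, item-level (partial) missingness, missingness correlated
with symptom state. Passing recovery tests therefore show the estimators are
correct under the stated model, not that real EMA data satisfy that model.

Study-condition defaults used by the recovery suite: 9 items, 3 factors,
n = 120 scheduled occasions at 80% completion (96 used), simple-structure
loadings in 0.4–0.9. The "well-separated" variant fixes loading levels
(≈0.88/0.68/0.42) and autoregressions (0.70/0.45/0.25, one 0.25 cross) so
per-factor variance-share gaps are at least 0.08 and path gaps at least 0.2 —
the regime in which recovering the generating factor ranking end-to-end is a
fair demand. Over 50 seeds the suite checks median per-factor Tucker
congruence ≥ 0.90, median path RMSE ≤ 0.15, and ranking recovery in ≥ 90% of
seeds; these sizes run in seconds on one core.

## Worked-case fixture

`participant021_fixture` transcribes a published three-factor worked case:
nine retained items with their salient loadings, variance shares 30/24/22%, an
NA autoregression of .58 and an NA→Worry cross of .26. The case's remaining
inputs were never printed; the fixture fills them with clearly labeled
synthetic placeholders (Worry and Fatigue autoregressions 0.40 and 0.64; item
means with the anhedonia/maximum ratio fixed at the reported 0.67), chosen
once so the case's qualitative facts hold — NA is the strongest factor and
normalizes to exactly 1. Tests that validate against published values never
touch the placeholders, and the full plan for this case is not exactly
recomputable from printed inputs alone.

## Known limitations

- Listwise deletion and MCAR assumptions; no imputation.
- χ² fit indices ignore serial dependence (warning emitted, see above).
- Per-equation OLS gives no joint covariance across equations; p-values are
  asymptotic and n ≈ 100 is modest.
- No cutoff below which a weakly scored module is dropped: any positive final
  score enters the plan. Choosing such a cutoff is an open research question.
- The item–module matrix encodes one clinical consensus; results are only as
  good as that mapping, which is why it is a replaceable plain CSV.
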