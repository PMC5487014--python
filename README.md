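# dataplan

Personalized, modular treatment planning from intensive repeated-measures
symptom data.

`dataplan` implements a fully quantified pipeline that turns one participant's
ecological momentary assessment (EMA) record — four short phone surveys a day
for a month, each symptom rated on a 0–100 visual-analog slider — into an
ordered plan of cognitive-behavioral treatment modules (the eight modules of
the Unified Protocol for Transdiagnostic Treatment of Emotional Disorders).
It is aimed at researchers in idiographic psychopathology and personalized
intervention who want every treatment-selection decision to be parameterized,
reproducible and falsifiable rather than settled by clinical consensus.

## The model

Three fitted/derived layers feed a deterministic scoring chain:

1. **Person-specific (P-technique) factor analysis.** The participant's
   occasions × items matrix is factor-analyzed (maximum-likelihood extraction
   on the Pearson correlation matrix, oblimin rotation), yielding standardized
   loadings λ, per-factor shares of total symptom variance, and TLI/CFI/SRMR
   fit indices. Avoidance items enter via a two-step test: they are kept only
   if they raise the explained variance share without degrading fit
   (CFI ≥ .95, TLI ≥ .95, SRMR ≤ .08).
2. **Lag-1 dynamic factor model.** The series is factor-scored (Thurstone
   regression scores) and each factor at occasion *t* is regressed on all
   factors at *t−1*. Standardized betas give autoregressions (diagonal) and
   cross-predictions (off-diagonal); non-significant crosses are pruned at
   α = .05, autoregressions always retained.
3. **Scoring chain.** With *N* factors, retained outgoing paths β and
   variance shares *V_f*:

   - raw factor score  `FS_f = V_f · (AR_f² + Σ β²_{f→g}) / N`
   - normalized  `FS_N = FS / max FS`  (the strongest factor scores exactly 1)
   - raw item score  `IS_i = (mean_i / max mean) · Σ_f FS_N,f · |λ_{i,f}|`
   - normalized  `IS_N = IS / max IS`
   - per module *m* with matched, retained items *S_m*:
     raw sum `Σ_{i∈S_m} IS_N,i`, item average `raw sum / |S_m|`, and
     `final_m = (norm(item avg) + norm(raw sum)) / 2`

   Modules with `final > 0` are ordered descending into the plan. Module 1
   (motivation enhancement) is prepended when compliance flags fire (reminder
   call, completion < 80%, or more than 30 days to reach the required survey
   count); Module 8 (relapse prevention) is appended for recurrent diagnoses.

A bundled binary item–module matching matrix (13 items × Modules 2–7) declares
which modules target which symptoms; it is a plain CSV and can be replaced to
re-target the algorithm at other item pools or module systems.

A seeded synthetic-data generator (`dataplan.synthetic`) produces EMA series
with known loading matrices, stationary VAR(1) factor dynamics and
missing-at-random occasions, so the whole pipeline is testable end-to-end
against ground truth without any participant data.

## Worked example

The bundled worked case (`participant021_fixture`) is a three-factor solution
— negative affect (NA), worry, fatigue — with variance shares 30/24/22%, an NA
autoregression of .58 and one NA→Worry cross-prediction of .26:

```python
import dataplan as dp

solution, dynamics, stats = dp.participant021_fixture()
raw = dp.raw_factor_scores(solution, dynamics)
print(raw.round(4).to_dict())
# {'NA': 0.0404, 'Worry': 0.0128, 'Fatigue': 0.03}
print(dp.normalize(raw).round(3).to_dict())
# {'NA': 1.0, 'Worry': 0.317, 'Fatigue': 0.743}

scores = dp.compute_scores(solution, dynamics, stats, dp.default_matrix())
print(scores.final_module.round(3).to_dict())
# {2: 0.991, 3: 0.893, 4: 0.595, 5: 0.602, 6: 0.621, 7: 0.0}
plan = dp.build_plan(scores, dp.ComplianceRecord(96, 120), dp.DiagnosisRecord(False))
print(plan.plan_string)
# 2-3-6-5-4
```

NA's raw score is `0.30 × (0.58² + 0.26²) / 3 = 0.0404`; being the largest, it
normalizes to exactly 1. The anhedonia item ("Experienced loss of interest or
pleasure", normalized mean .67, loading .42 on NA) pulls Module 5 into the
plan even though no clinician selected an anhedonia intervention for this
case. Module 7 scores 0 — no exposure-matched item survived the factor
analysis — so it is excluded. A .58 standardized path means
`dp.variance_explained(0.58) == 34` percent of next-occasion variance.

From the shell, the same pipeline runs end to end on simulated or real data:

```bash
dataplan run-all --seed 11 --out report.json
# plan: 4-3-2-7-5-6
dataplan score --loadings L.csv --dynamics D.csv --means M.csv \
               --recurrent --out plan.json
```

`report.json` carries the full audit trail: loadings, variance shares, fit
indices, the pruned path matrix, all three module-score variants and the plan.

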