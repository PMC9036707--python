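# adjiv — adjusted instrumental-variable analysis on simulated hospital cohorts

`adjiv` is a simulation framework for studying when **treatment-preference
instrumental-variable (IV) analysis** gives valid treatment-effect estimates
from observational hospital data — and when it does not.

## The problem

Comparative-effectiveness questions (the motivating example is
intracranial-pressure monitoring in severe traumatic brain injury) often
cannot be answered by trials, and observational estimates suffer from
*confounding by indication*: sicker patients are treated more often and do
worse. Covariate or propensity-score adjustment handles only *measured*
severity. Using a hospital's treatment preference — the proportion Z of its
patients treated — as an instrument promises to bypass unmeasured
confounding, but breaks down when the instrument shares a *common cause*
with the outcome, e.g. when hospitals that prefer the treatment are also
better hospitals. The **adjusted IV** strategy studied here additionally
conditions the outcome model on the hospital, capturing that common cause.

## What the package does

It generates hospital-clustered cohorts and compares six estimation
strategies, all fitted with proportional-odds (cumulative-logit) models
built into the package:

| | strategy | model | reported coefficient |
|---|---|---|---|
| a | univariable | logit P(Y≤k) = α_k + Tβ_T | β_T |
| b | covariate adjustment | α_k + Cβ_C + Tβ_T | β_T |
| c | propensity-score adjustment | α_k + PS·β_PS + Tβ_T, PS from logistic T~C | β_T |
| d | IV | α_k + Zβ_Z | β_Z |
| e | adjusted IV | α_k + Zβ_Z + Hβ_H | β_Z |
| f | fully adjusted IV | α_k + Zβ_Z + Hβ_H + Cβ_C + Uβ_U | β_Z |

Data generation (per replication): patients receive prognostic factors
(GCS motor score, age, sex = observed C; pupillary reactivity, SAH, Marshall
CT class = hypothetically unobserved U) from configurable marginals; each of
100 hospitals receives a treatment preference p_h ~ Uniform(0.17, 0.58) and
a performance effect η_h, correlated through a Gaussian copula; treatment is
Bernoulli in C, U and a calibrated hospital offset so each hospital treats
a share ≈ p_h; and a 4-level ordinal outcome (1 = death/vegetative … 4 =
good recovery) follows a proportional-odds model with a beneficial true
treatment coefficient β_T = −0.5 (benefit odds ratio e^0.5 = 1.65).
Seven pre-registered scenarios switch confounding, preference, and the
preference–performance common cause on and off.

## Worked example

```python
from adjiv import simulate_dataset, estimate_effect, instrument_relevance

ds = simulate_dataset(n_patients=15_000, scenario=6, seed=123)
print("treated fraction:", round(ds.t.mean(), 3))
print("instrument relevance R2:", round(instrument_relevance(ds), 3))
for s in "abdf":
    e = estimate_effect(s, ds)
    print(f"strategy {s}: beta = {e.beta:+.3f} (SE {e.se:.3f}) [{e.estimand}]")
```

prints

```
treated fraction: 0.363
instrument relevance R2: 0.081
strategy a: beta = +0.007 (SE 0.031) [treatment_effect]
strategy b: beta = -0.187 (SE 0.033) [treatment_effect]
strategy d: beta = -0.398 (SE 0.128) [preference_effect]
strategy f: beta = -0.495 (SE 0.130) [preference_effect]
```

Scenario 6 contains unmeasured confounding plus an active preference: the
unadjusted estimate (a) loses the beneficial effect entirely, covariate
adjustment (b) only partially corrects it, while the IV strategies (d, f)
land near the simulated −0.5 — at the price of a four-times-larger standard
error. (Strategy f also warns that the hospital-performance adjustment
column is degenerate here: scenario 6 has no hospital performance effect,
so the collinearity screen drops it and reports that it did.)
Strategies d–f estimate the effect of the treatment *preference* (the
coefficient on Z); the calibration puts Z on the treatment-probability
scale, which makes β_Z directly comparable to β_T.

The full Monte-Carlo study (scenarios × correlation sweep × replications):

```bash
adjiv simulate --scenario 6 --scenario 7 --reps 500 --seed 42 --out results/
adjiv report --in results/ --format csv
```

writes `summary.csv` (mean β̂, mean model SE, empirical SD per scenario ×
rho × strategy), `estimates.csv` (one row per replication × strategy),
`histogram_d_e.csv` (binned IV and adjusted-IV point estimates) and
`run.log`.

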