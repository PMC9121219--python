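# drawcog

Analysis of the *drawing process* — not the drawn product — as a digital
biomarker of global cognition in older adults. The package simulates raw
digitizer pen streams for two demographically distinct cohorts, extracts
six kinematic drawing features, reproduces a covariate-adjusted
correlation analysis between the features and a 0–30 global-cognition
screening score (MoCA-like), and evaluates a hyperparameter-tuned random
forest that estimates the score on a cohort it was never trained on,
with permutation-based inference and Shapley feature attribution.

It is aimed at researchers in digital phenotyping and computational
neuropsychology who want a fully reproducible, synthetic-data testbed
for cross-cohort validation of drawing-based cognitive assessment.

## The model

Each drawing session is a pen-event time series sampled at 180 Hz on a
252 × 186 mm surface: position (x, y), normalized pressure, pen
inclinations, and hover distance. A trail-making-like task (25 targets,
24 connecting strokes) is summarized by six features:

| feature | definition |
|---|---|
| `speed_mean` | mean of instantaneous pen-tip speeds v_i = ‖Δ(x,y)‖/Δt within strokes (mm/s) |
| `speed_cv` | coefficient of variation of the v_i (sample SD / mean) |
| `pressure_mad` | median absolute deviation of on-surface pressure (raw MAD, no consistency constant) |
| `incl_h_sd`, `incl_v_sd` | sample SDs of the pen's horizontal / vertical inclinations (degrees) |
| `pause_ratio` | total pause time ÷ active drawing time; pauses are pen-up gaps between strokes plus within-stroke dwells where the tip stays inside a 0.25-mm radius for > 100 ms |

Associations with the cognition score y are measured by partial Pearson
correlations: residualize the feature and y on age, sex and years of
education, correlate the residuals, test with t = r·√((n−2−k)/(1−r²))
on n−2−k df, and control the six-test family with Benjamini–Hochberg.

The regression component is a scikit-learn-style estimator,
`DrawingForestRegressor`: a 500-tree random forest tuned by exhaustive
grid search over max_depth ∈ {2,3,4}, max_features ∈ {2,3,4,6},
bootstrap sample fraction ∈ {1.0, 0.75, 0.5} and min_samples_leaf ∈
{2,3,4,5} (144 candidates) under seeded 10-fold cross-validation,
selecting the lowest mean CV squared error. Generalization is evaluated
on the held-out cohort (R², Pearson r, MAE, RMSE), significance by
permuting training labels (p = (1 + #{null ≥ observed})/(1 + B)), and
feature importance by exact interventional Shapley values computed by
full enumeration of the 2⁶ feature coalitions.

The synthetic generator draws the cognition score first, standardizes it
within-cohort, and maps it linearly on the log scale to the kinematic
generating dispersions, so that each feature attains a configurable
target correlation with the score (see `docs/methods.md`).

## Worked example

```python
import pandas as pd
from drawcog import (CohortConfig, DeviceProfile, DrawingForestRegressor,
                     EffectConfig, FEATURE_NAMES, HyperparameterGrid,
                     evaluate, extract_features, feature_moca_table,
                     generate_cohort, permutation_test)

device = DeviceProfile()                      # 180 Hz, 252 x 186 mm
effect = EffectConfig()                       # calibrated cognition linkage

def records(cohort, seed):
    rows = []
    for stream, meta in generate_cohort(cohort, effect, device, seed=seed):
        meta.update(extract_features(stream).as_dict())
        rows.append(meta)
    return pd.DataFrame(rows)

us = records(CohortConfig.us_like(100), seed=1)
japan = records(CohortConfig.japan_like(100), seed=2)
both = pd.concat([us, japan], ignore_index=True)

print(feature_moca_table(both, "all").round(3).to_string(index=False))

grid = HyperparameterGrid(max_depth=(2, 3, 4), max_features=(2, 6),
                          max_samples=(1.0,), min_samples_leaf=(5,),
                          n_estimators=100)   # reduced grid for the example
model = DrawingForestRegressor(grid=grid, cv=10, random_state=0)
model.fit(us[list(FEATURE_NAMES)], us["moca"].astype(float))
metrics = evaluate(model, japan[list(FEATURE_NAMES)], japan["moca"].astype(float))
perm = permutation_test(model, us[list(FEATURE_NAMES)], us["moca"].astype(float),
                        japan[list(FEATURE_NAMES)], japan["moca"].astype(float),
                        n_permutations=200, seed=0)
print(f"R2={metrics.r2:.3f} r={metrics.pearson_r:.3f} "
      f"MAE={metrics.mae:.3f} RMSE={metrics.rmse:.3f} p={perm.p_value:.4f}")
```

Output:

```
     feature   n      r  ci_low  ci_high     p  p_bh
  speed_mean 200 -0.024  -0.163    0.116 0.740 0.740
    speed_cv 200 -0.478  -0.579   -0.362 0.000 0.000
pressure_mad 200 -0.367  -0.482   -0.240 0.000 0.000
   incl_h_sd 200  0.381   0.255    0.495 0.000 0.000
   incl_v_sd 200  0.123  -0.017    0.258 0.086 0.103
 pause_ratio 200 -0.465  -0.568   -0.348 0.000 0.000
R2=0.417 r=0.675 MAE=1.632 RMSE=2.103 p=0.0050
```

Reading the table: lower cognition scores go with more variable speed
and pressure, more pausing, and less inclination variability — exactly
the configured sign pattern — and the correlations survive covariate
adjustment and BH correction. The forest trained on the older,
US-like cohort explains ~42% of score variance in the unseen,
younger Japan-like cohort; none of 200 label permutations reached the
observed R², so p hits its minimum of 1/201.

A CLI mirrors the library (`drawcog simulate | extract | correlate |
train-eval | run-all`); `drawcog run-all --out run1/` writes a JSON
report plus CSV side tables, driven by a single YAML config.

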