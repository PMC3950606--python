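# mguard — mate-guarding energetics for wild primates

`mguard` turns raw field data on wild male macaques — minute-resolution
focal scans, GPS tracks, monthly fruit-phenology surveys, daily rainfall,
urine assays and a bared-teeth interaction matrix — into daily
behavioural and energetic metrics, and asks whether mate-guarding (MG)
carries an energetic cost: does the share of a day a male spends
guarding a female predict his feeding time, fruit intake, travel,
climbing, restlessness, or urinary C-peptide (UCP, a non-invasive index
of energetic status)?

It is written for behavioural ecologists and field endocrinologists who
have (or want to simulate) focal-animal scan data with the classic
"alpha/beta males guard females in multi-male groups" design.

## What it computes

**Mate-guarding segmentation.** A male is guarding when he follows a
female at ≤ 10 m for more than five consecutive minutes; losing her for
up to 2 min does not end the episode (a third minute does, and the end
is back-dated to the last qualifying minute). Days with MG > 50 % of
observation time are *extensive* MG days; runs of consecutive extensive
days form MG periods.

**Daily metrics.** Activity budgets with feeding precedence over
non-exclusive states, diet composition over feeding scans, restlessness
(the fraction of consecutive minute pairs in which locomotion/position
changes, 0–1), horizontal travel from GPS fixes subsampled every
15 ± 5 min (hourly distance = 4 · ΣDᵢ/n, which cuts the spurious
path-length from ±10 m GPS noise from ~600 to ~40 m/h), and vertical
travel from canopy-height category midpoints (0, 3, 7.5, …, 27.5 m).
Male-days with under one hour of coded focal data are dropped.

**Covariates.** Monthly fruit availability per territory (% of ~120
surveyed trees fruiting, assigned to days via 16th-to-15th windows),
daily rainfall, creatinine-indexed UCP (ng/mg) with assay-sensitivity
and >8-month-storage exclusions, and an I&SI dominance order from the
bared-teeth matrix (high rank = alpha/beta).

**Inference.** For each response *y* (daily feeding %, fruit-in-diet %,
hourly distance, hourly vertical distance, restlessness; per-sample
UCP):

  y ~ β₁·MG% + β₂·fruit + β₃·rain (+ controls) + AC
      + (1 | group) + (1 | male:group) + ε,   fitted by ML,

with continuous predictors z-standardized and a temporal
autocorrelation covariate AC (Gaussian-kernel-weighted mean of the same
male's residuals from the null-structure fit, kernel width chosen from
a fixed grid by full-model likelihood). Each full model is compared
with its null (same structure minus the tested term) by likelihood-
ratio test; VIFs check collinearity.

**Synthetic study.** `mguard.simulate` generates a complete raw study
with known ground truth — scans, error-laden GPS, phenology, rainfall,
urine, interaction matrices — at the footprint of a two-mating-period,
3-group, 6-focal-male field study, with configurable planted effects,
so the whole pipeline is testable end to end without any field data.

## Worked example

```sh
mguard pipeline --seed 1 --out demo --models feeding,vertical,ucp_mg
```

simulates a study, segments MG, assembles the male-day table and fits
the selected models. The run prints:

```
   model   n  lrt_chi2  lrt_df  lrt_p  converged
 feeding 599    596.49       1  0.000       True
vertical 599    506.29       1  0.000       True
  ucp_mg 145      0.00       1  0.964       True
```

Read: across 599 retained male-days, dropping MG% from the feeding and
vertical-travel models costs a highly significant amount of likelihood
(the generator plants negative standardized effects of −2 and −1.8 on
those responses), while the UCP model's full-vs-null test is null — the
generator's UCP effect is 0, mirroring the finding that guarding males'
energetic status is unchanged. `demo/fit_feeding.json` carries the
estimates ± SE, the AC kernel width, and the VIFs; `demo/provenance.json`
records the seed and config hash. Reruns with the same seed are
byte-identical.

The same steps are available as a library:

```python
from mguard import simulate, tables, phenology, inference

study = simulate.generate_study(simulate.StudyConfig(seed=1))
daily = tables.daily_metrics(study.scans, study.gps)
table = tables.build_model_table(
    daily, phenology.monthly_indices(study.phenology), study.rainfall,
    study.territory_of_male, study.group_of_male)
res = inference.GuardingModel.from_dataframe(table, "feeding").fit()
print(res.summary())
```

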