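# Methods

This note documents the models, conventions and numerical choices in
`mguard`, and what the synthetic-data tests do and do not establish.

## Episode segmentation

Scans arrive at 1-min resolution with, per minute, the followed female
(if any) and whether she was within 10 m. A minute *qualifies* for
female F when both hold. An episode opens at the first minute of a run
of ≥ 6 consecutive qualifying minutes ("more than five minutes",
strictly read), tolerates at most two consecutive non-qualifying
minutes once open, closes on the third, and is truncated back to the
last qualifying minute. Conventions the raw definition leaves open:

- **Missing minutes and missing distance flags** count as
  non-qualifying grace minutes. This is conservative: absence of
  evidence never extends guarding.
- **Female switches** close the running episode (through the grace
  rule) and open a new episode once the new female accumulates her own
  six-minute run. Episodes can therefore never overlap: an open
  episode's grace allows ≤ 2 foreign minutes, while a new episode needs
  6.
- **MG minutes for day summaries** count *observed* minutes inside
  episode spans, so the MG fraction is a genuine share of observation
  time and can never exceed 1 even when an episode bridges an
  observation gap.
- **Extensive days** use a strict > 50 % cut; exactly half does not
  count. **MG periods** are runs of extensive days in which unobserved
  calendar days do not break the run (groups were followed every other
  day in part of the study, so calendar-strict runs would be
  impossible); only observed extensive days count toward period length.

The segmenter is a state machine; tests hold it against an independent
regular-expression formulation (`q{6,}(\.{1,2}q+)*` per female) on 10⁴
random days.

## Daily metrics

Denominators are coded focal minutes (rows not marked out-of-sight; a
flag switches this). Feeding precedence: any minute carrying a food
item counts as feeding, whatever concurrent non-exclusive state
(grooming, self-grooming, travelling) was coded — the analysis is about
energy, so ingestion wins. Raw (precedence-free) budgets remain
available. Restlessness pairs each coded minute with its immediate
predecessor; pairs across gaps are dropped, so the first minute of each
contiguous block contributes nothing. Days with < 60 coded minutes are
excluded from all downstream tables.

## Movement

Travel is computed on fixes subsampled greedily: from the first
eligible fix (eligibility = focal behaviour coded at that minute), the
next fix is the eligible one nearest to +15 min within ±5 min, earlier
fix on ties; an empty window breaks the chain and no segment spans the
break. Hourly distance is 4 · ΣDᵢ/n over the ~15-min displacements.
The analytic error model — a stationary animal with mean spurious
consecutive-fix displacement e at interval m minutes accumulates
(60/m)·e metres per hour — gives 600 m/h at (1 min, 10 m) and 40 m/h at
(15 min, 10 m); the Monte-Carlo mode draws isotropic Gaussian fix
errors with per-axis σ = e/√π so the mean consecutive displacement is
exactly e.

Vertical travel converts height categories to band midpoints. Category
6 ("> 25 m") is open-ended; its midpoint is set to 27.5 m, continuing
the 5-m band width (a sensitivity flag exists in the conversion table).
The daily metric is Σ|Δheight| over consecutive coded pairs per coded
hour; an ascent-only mode and a per-minute mean are also emitted, and
the models use the per-hour sum.

## Phenology, endocrinology, dominance

Fruiting = score ≥ 1 on the 0–5 log-abundance scale; the monthly index
is the percentage of a territory's surveyed trees fruiting, dated to
month-end and assigned to days from the 16th of that month through the
15th of the next. UCP is C-peptide (ng/ml) over creatinine (mg/ml);
samples with creatinine below the 0.1 mg/ml assay sensitivity are
flagged out, and samples stored frozen > 8 months (strictly) before
lyophilisation are excluded; the two filters commute. Dominance uses
I&SI on the bared-teeth matrix — the display is submissive, so the
*receiver* outranks the giver; undecided dyads (ties, 0–0) score
nothing. The optimiser is a pairwise-swap descent from 30 seeded
starts including the identity order; exhaustive search is the test
oracle at n ≤ 8. Ranks 1–2 are "high", the rest "low".

## Mixed models

Each response is Gaussian with random intercepts for group and for
male within group, fitted by maximum likelihood so full and null models
are LRT-comparable. Continuous predictors are z-standardized (sample
SD) over exactly the rows entering the fit. The predefined battery:
five behavioural models (feeding %, fruit-in-diet %, hourly distance,
hourly vertical distance, restlessness ~ MG% + fruit + rainfall, MG ×
fruit interaction fitted first and dropped when its LRT p > 0.05) and
two UCP models (UCP ~ MG% + fruit + rainfall + collection time +
storage + vertical travel + feeding %; UCP ~ rank class + fruit +
collection time + storage). The UCP models carry no autocorrelation
term: urine samples are sparse (~weekly), so day-to-day residual
correlation has little to bite on.

**Autocorrelation covariate.** For the behavioural models, residuals
from the null-structure fit without the AC term are smoothed per male
with Gaussian weights exp(−Δd²/2σ²) over all *other* days; σ is chosen
from {0.5, 1, 2, 4, 8, 16} days by full-model likelihood. Rows without
a same-male neighbour get 0. The exact published variant of this
residual-autocorrelation device is not specified anywhere; this
implementation is isolated behind `build_ac_term` so alternatives
(causal kernels, pre-whitening) can be swapped in.

**Known property.** Conditioning on a response-derived covariate can
in principle make the χ²₁ reference for other terms anticonservative.
With the implemented variant (null-fit residuals, grid-selected σ) the
full-vs-null test measures a type-I error of 0.06 over 1,000 null
simulations at study scale with AR(1) residuals (ρ = 0.4), with a
p-value distribution indistinguishable from uniform; the acceptance
suite re-runs this check. Variants that smooth *full*-model residuals
drifted slightly higher in the same simulations and were rejected.

**Numerics.** MixedLM likelihoods are optimised with Powell's method
(gradient-based optimisers stall before the optimum on these
small-cluster likelihoods often enough to corrupt full-vs-null
likelihood differences; fits were cross-checked against lme4). χ² is
clipped at 0; df = number of dropped fixed-effect parameters. VIFs come
from OLS of each predictor on the others, flagging ≥ 5; with only 3
groups and 6 males a small-cluster warning is always emitted because
the variance components are weakly identified.

## Synthetic study

The generator emulates the study conditions: 3 groups, 2 focal
(alpha/beta) males each plus 2 urine-control males, ~180 calendar days
followed on an alternate-day schedule (every day during MG periods),
observation days of 90–420 min with occasional sub-hour days, per-male
target MG time spread over ~8–54 % of observation time, MG days in
Markov-chain blocks (continue probability 0.72, mean period length ≈ 4
observed days), episodes ≥ 6 min separated by ≥ 3 min so segmentation
recovers them exactly. Daily responses are built on the standardized
scale — planted β·z(MG) + fruit effects + group/male intercepts + AR(1)
day residuals (ρ = 0.4 by default) — then realised as minute-level
multinomial/Markov draws (feeding probability, fruit share, locomotion
switching, height-category steps), GPS as a correlated random walk plus
isotropic error, UCP lognormal with a zero MG effect by default (the
study condition), phenology from a seasonal per-tree fruiting model,
and a bared-teeth matrix from a planted linear hierarchy with rare
reversals.

Planted default effects (standardized): feeding −2.0, fruit-in-diet
−1.5, vertical −1.8, distance 0, restlessness 0, UCP 0 — matching the
qualitative study outcome (feeding, diet and climbing respond; distance,
restlessness and energetic status do not).

What the synthetic tests show: the pipeline reduces raw files to
exactly the generator's bookkeeping, and the inference layer recovers
table-level planted effects without bias. What they do not show:
robustness to real-data pathologies — observer drift, mis-identified
females, GPS multipath, heteroscedastic behaviour (a `misspecified`
mode adds MG-dependent residual variance for robustness checks, but it
is not the default), or diurnal activity structure, which the generator
does not emulate.

Two generators exist deliberately: `generate_study` (full raw-file
fidelity, used for pipeline integration tests at moderate scale) and
`generate_model_table` (direct male-day simulation at study scale of
~580 rows, used for the 100–1,000-replicate inference calibration and
recovery runs, where full minute-level generation would be wasteful —
the responses there carry the planted effects exactly, with
sample-standardized predictors, so recovery is a clean test).

## Degenerate inputs and tie-breaks

Zero coded minutes, no feeding scans, < 2 consecutive pairs, zero
track segments: all raise an explicit undefined-day signal (or yield
NaN in bulk reduction, dropped later by the model). Constant columns
refuse standardization by name. Subsampling ties go to the earlier
fix; swap-descent ties to the lowest index pair; identical LRT specs
give χ² = 0, p = 1. Perfect collinearity reports infinite VIF rather
than an exception.
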