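# Methods

`hcpmeta` implements the quantitative machinery used in secondary analyses
of healthcare-provider (HCP) performance-improvement reviews: effect sizes
in absolute percentage points, median-effect-size (MES) summaries per study
comparison, rule-based risk-of-bias categories, and clustered random-effects
models of training attributes. This note documents the models, the
parameters that matter, the synthetic-data generator the tests rely on, and
the numerical choices made where the design was genuinely open.

## Effect sizes

The unit of analysis is the absolute percentage-point (%-point) change,
oriented so that positive values always mean improvement (effects of
outcomes that decrease to indicate improvement — e.g. % of patients given
unnecessary antibiotics — are multiplied by −1).

For non-ITS designs, measurement selection uses the baseline closest in
time to the strategy start and the follow-up furthest from it. With
intervention-arm values `b_i, f_i` and reference-arm values `b_c, f_c`:

* percentage outcomes: `ES = (f_i − b_i) − (f_c − b_c)` with baselines,
  `ES = f_i − f_c` without;
* unbounded continuous outcomes: `ES = 100·[(f_i − b_i)/b_i − (f_c − b_c)/b_c]`
  with baselines, `ES = 100·(f_i − f_c)/f_c` without. These relative-change
  forms are *undefined* (a status, not an exception) exactly when a required
  denominator is zero; such records are excluded with a machine-readable
  reason.

Percentage effect sizes whose intervention-arm baseline is ≥ 95% are
excluded (little room for improvement). The boundary is inclusive, the rule
tests the raw baseline value, and a config switch (`ceiling_rule="either"`)
extends the test to either arm; with the default rule a reference-arm
baseline at the ceiling only logs a warning. Ties in measurement selection
resolve to the first row in file order, with a warning, so runs are
deterministic and auditable.

The diff-in-diff percentage form is antisymmetric under arm exchange and
translation-invariant; the continuous forms are antisymmetric except the
no-baseline variant, whose denominator is arm-specific. Tests assert these
properties where they hold exactly.

## Interrupted time series

Each ITS series is fit by unweighted OLS to
`Y_t = β0 + β1·t + β2·post_t + β3·t·post_t` with `t` in months centred at
the strategy start (`post_t = 1` for `t ≥ 0`). The summary effect is the
predicted level at the midpoint of the follow-up period minus the
counterfactual from the extended pre-trend, which under this
parameterisation equals `β2 + β3·midpoint` identically. Controlled ITS
takes the difference of the two arms' summary effects; uncontrolled ITS
uses the intervention arm alone (its own pre-trend is the counterfactual).

A minimum of 3 pre and 3 post points is required — the smallest counts that
identify two slopes and leave a residual degree of freedom. No
autocorrelation correction is applied (the residual SD is descriptive; a
Newey–West-style option exists as a disabled stub). Degenerate time grids
raise an estimation error rather than returning a rank-deficient fit.

## Risk of bias

Designs start at low (randomised), moderate (ITS, with or without control)
or high (non-randomised) risk, then drop one level per applicable "not
done" domain and one level per *complete pair* of applicable "unclear"
domains (floor division — an odd leftover does not drop), clamped at very
high. "Not applicable" domains are excluded from both counts. The rule is
tested against an exhaustive enumeration oracle.

## Comparisons and summaries

Arm strategies are classified into five mutually exclusive training
categories plus eleven other component categories; printed materials
bundled with a training course are absorbed into the training
classification. Five comparison types are enumerated (training vs control;
training vs training; training+X vs X; trainingA+X vs trainingB+X with
identical X, enforced as strict set equality; and equivalency against a
gold-standard arm). Multi-arm studies emit every valid pairing; for
head-to-head types the deterministic intervention/reference direction
follows the canonical training-category order. Equivalency comparisons are
never pooled with the others — they are reported separately with |MES| as
the success metric.

Effect sizes within one comparison (and outcome scale) collapse to their
median (MES). Distribution summaries report median, IQR, minimum and
maximum with quantiles by linear interpolation between order statistics
(numpy default, R type 7) — a documented convention so that R and Python
reproductions can match bit-for-bit. Strata with fewer than three
comparisons suppress the IQR, and singleton strata also suppress the range,
mirroring how sparse strata are conventionally reported. Cost analysis
divides total cost by (HCPs trained × training days) and summarises the
per-arm values the same way.

## Attribute modelling

The dependent variable is the outcome-level effect size (not the MES). The
model is a linear mixed model with a study-level random intercept, REML
estimation, unweighted observations — the minimal structure that accounts
for clustering of multiple outcomes per study. Three nested databases are
modelled: training alone; training with or without supervision; training
with or without any other components (the widest tier adds eleven
non-training component presence indicators, a deliberately simple
adjustment). Rows are restricted to percentage outcomes, professional HCPs,
group in-service training, and durations under 20 days (missing durations
retained).

Confounders — baseline performance level (centred at 50 %-points) and time
since training — are always included. For decrease-improves percentage
outcomes the baseline *performance* is 100 minus the raw baseline value;
the model uses this oriented scale while the ceiling rule keeps the raw
one. Missing continuous covariates are zero-filled with an indicator;
missing categorical attributes get an explicit "missing" dummy; rows are
never dropped for missingness. No multiple-testing adjustment is applied —
p-values are labelled screening quantities.

Reported fit quality is an adjusted R² defined as the squared correlation
between observed effects and fixed-effects-only predictions, adjusted by
`1 − (1−R²)(n−1)/(n−p−1)` with `n` effect sizes and `p` fixed covariates;
mixed-model R² has no canonical definition, so this one is stated and
tested. The waning horizon divides the mean predicted effect at time zero
by the magnitude of the (negative) time slope; a non-negative slope returns
"no waning". Head-to-head (direct) evidence is summarised per contrasted
attribute beside the model's indirect estimates, with attributes lacking
any head-to-head study reported as "none".

Numerical care: constant design columns are dropped; linearly dependent
dummies (common in small tier tables) are pruned by QR with column
pivoting; the optimiser falls back lbfgs → powell → cg on linear-algebra
failures; and deterministic (zero-residual) data, which have no REML
surface, return the least-squares fit with zero variance components and a
warning. Boundary (zero) random-effect variance is retained, with a
warning, rather than treated as failure.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes. The
oriented true effect of outcome *k* in study *j* at follow-up time *t*
(months) with baseline *b* is

```
es_jk = μ + Σ_a β_a (x_aj − p_a) + w·(t − 4) + g·(b − 50)·[percentage] + u_j + e_jk
```

with defaults chosen to mirror the review-scale conditions the pipeline is
meant for: median effect 7.3 %-points; on-site training β = +8 and clinical
practice β = +7 %-points; waning w = −0.9 %-points/month; baseline gradient
g = −0.13 %-points per %-point; follow-up lognormal with median 4 months
(IQR ≈ 2–7.5); about five outcomes per comparison; 15% ITS, 5% lay-HCP,
15% continuous-scale outcomes. The between-study effect u_j is
double-exponential (Laplace) by default, variance-matched to
`between_study_sd = 8`, reproducing the heavy tails of observed effect-size
distributions; within-study noise (SD 4) and per-measurement noise (SD 1)
are Gaussian. Between- and within-study variance components are free
parameters of the generator, documented as such.

The intercept μ is `effect_median` minus a Monte-Carlo median offset of the
non-intercept components (computed on a fixed internal stream), so the
empirical median of true effects converges to the configured
`effect_median` even though the skewed covariate contributions are only
mean-centred.

Measurement values are constructed by *exactly inverting* the effect-size
equations the engine applies (including ITS series, whose level change is
set so the segmented summary equals the target), so with all noise at zero
the full pipeline reproduces every configured effect to machine precision —
the conservation-of-signal property the degenerate-noise tests assert.
Percentage measurements are clipped to [0, 100]; clipping events are
counted per outcome in the ground truth and logged. One random stream is
derived per study from `(seed, study index)`, so enlarging a database never
perturbs existing studies, and a fixed seed yields byte-identical CSVs.

What the generator does **not** emulate: publication bias or screening,
report text, lay-HCP-specific null effects, informative missingness,
autocorrelated ITS noise, or outcome-specific measurement error scales.
Passing tests therefore demonstrate correctness of the machinery under the
stated statistical structure, not robustness to every feature of real
review data. Saturation at the percentage bounds does occur (and is
logged); it induces the small attenuation one expects in real bounded
outcomes.

## Problem sizes used in the test suite

Recovery experiments use 200 replicate databases of 150 studies for the
coefficient-recovery and coverage checks, a 400-study database for the
waning-horizon recovery, 2000 studies for the median-convergence check, and
25–60 studies for end-to-end and conservation tests. The acceptance script
analyses one 199-study portfolio and 24 replicate 150-study portfolios.
These sizes give Monte-Carlo error comfortably inside the asserted
tolerances while keeping a full run inexpensive on a single CPU.

## Known limitations

* The three-tier eligibility filter treats shared components as exact sets;
  partially overlapping component groups produce no comparison.
* Model-based (not sandwich) standard errors; a robust option is stubbed.
* The equivalency pathway is exercised by fixtures, not by the generator.
* The waning horizon is a linear extrapolation far beyond most observed
  follow-ups; it inherits all the fragility of such extrapolations and is
  sensitive to outliers.
* Cost summaries ignore inflation and exchange-rate adjustment; costs enter
  as recorded.
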