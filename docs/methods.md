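# Methods

## Model and pipeline

The package analyses long-format longitudinal exam tables: per subject and
visit an age, recorded height, recorded weight, recorded BMI, non-fasting
glucose, systolic/diastolic blood pressure and an antihypertensive
medication flag.  Subjects are eligible when they have at least one height
measurement at age ≤ 40 and at least one after 40 (the boundary age counts
as "young" for both the eligibility rule and the young-height mean, so the
two rules cannot disagree).

**Smoothing.**  For subjects with ≥ 4 exams, height-vs-age and BMI-vs-age
are smoothed with LOWESS — locally weighted degree-1 regression with
tricube weights over the `int(frac·n)` nearest neighbours (statsmodels
implementation, no robustness iterations).  The span defaults to
`frac = 0.6`; robustness is supplied instead by an explicit rejection rule:
a point is an outlier iff its absolute residual exceeds six times the
median absolute residual of the subject's own series (strict inequality,
"more than six times") *and* is at least 1 cm (height) or 0.2 kg/m² (BMI)
from the fit (inclusive, "at least").  The fit is then recalculated exactly
once without the flagged points and evaluated at all original ages, so
downstream per-age metrics remain defined at rejected ages.  If fewer than
four points would remain, rejection is abandoned (flags cleared, first fit
kept) — in practice this guard is unreachable for realistic contamination,
because flagging most of a series destroys the median the rule depends on;
the test suite checks the invariant property rather than the branch.
Series with < 4 points are passed through unsmoothed.  Recorded BMIs that
disagree with weight/(smoothed height)² by ≥ 5 units are excluded from the
BMI series before BMI smoothing.

**Quantities.**  Young height H₀ is the mean of the (smoothed when
available, outlier-excluded) heights at ages ≤ 40; a subject whose every
pre-40 height was rejected has no usable young height and is dropped (a QC
event, counted in the manifest).  Per exam: shrinkage = H₀ − H(t)
(reported as-is, slightly negative values possible under noise); current
BMI = the smoothed BMI series (the consistency-filtered recorded BMI where
unsmoothed); corrected BMI = W(t)/H₀²; excess BMI = current − corrected.
Excess BMI is oriented so that height loss makes it positive.

**Misclassification.**  Current and corrected BMI are categorised with
cutoffs 25 (overweight) and 30 (obese), boundaries inclusive at the lower
edge of each category.  "Wrong overweight" and "wrong obese" flags are
mutually exclusive by construction.  Fractions are computed per sex in
5-year age bins centred on multiples of 5 (bin 80 = [77.5, 82.5)); a
subject contributes one exam per bin — the exam nearest the bin centre —
to avoid double-counting.  Both denominators (whole population in the bin;
currently-in-category) are reported, plus the union ("either") under both
a population and an all-classified denominator, since the combined headline
figure has an ambiguous denominator.  An empty denominator yields an
undefined fraction (`None`/NaN with counts), distinct from an observed 0.

**Relative risk.**  Disease at an exam: pre-diabetes glucose ∈ (140, 200]
(strict at 140, so diabetics are excluded from the pre-diabetic band — the
band definition is the package's resolution of an ambiguity and is kept in
one place), diabetes glucose > 200, hypertension = medication ∨ SBP ≥ 140
∨ DBP ≥ 90.  Within each sex and age bin, RR = (events/n among obese) /
(events/n among non-obese), with "non-obese" meaning everyone below 30
under the chosen BMI definition (overweight included).  Zero events among
the non-obese or an empty stratum make the RR undefined (signalled, never
infinity); zero events among the obese give RR = 0.  A log-RR Wald
interval is attached for plotting only.  Prevalence at the exam, not
incidence, is used throughout.

**Trends.**  Shrinkage is pooled over all eligible subject-exams and fit
by OLS against years past age 35 (degree 1 and 2); "total loss 40→80" is
the fitted polynomial evaluated at age 80 minus at age 40.  Excess BMI is
fit linearly against age and, secondarily, against shrinkage (the
secondary fit is skipped when shrinkage is degenerate, e.g. identically
zero).  These are descriptive pooled fits; no per-subject random effects.

## Synthetic cohort generator

The generator emulates the measurement regime of a mid-20th-century
cardiovascular cohort and provides the ground truth the recovery tests
need.  Per subject: sex (female fraction 0.5), enrollment age ~ U(30, 38),
biennial exams to age 80 (so every subject is eligible by construction);
true young height ~ N(160.5, 6²) cm women / N(174.0, 6²) men; height
constant until onset age 40, then linear loss at a subject rate ~
N(0.12, 0.02²) cm/yr women / N(0.09, 0.02²) men, truncated at 0 — means
chosen so the mean 40→80 loss is 4.8 cm (women) and 3.6 cm (men).  Young
BMI ~ N(25.5, 3.5²) women / N(26.0, 3.5²) men truncated to [17, 35] /
[19, 35]; after onset the BMI trajectory drifts by +0.05 kg/m²·yr and
carries per-exam noise of sd 0.3 kg/m² (a value chosen once as typical
within-person variability).  Weight is derived from the BMI trajectory on
the *young* height, so the trajectory is the subject's corrected-scale
BMI, and "truly obese" at an exam means that value ≥ 30.  Truncated
normals use inverse-CDF sampling so the draw count is fixed and same-seed
runs with different parameter values stay aligned (needed for the
monotone-stress test).

Measurement model: recorded height = true height + N(0, 0.5²) cm, replaced
with probability 0.01 by a gross error of ± U(2.5, 10) cm, then floored to
the next lower quarter inch; recorded weight rounded half-up to the
nearest 5 lb; recorded BMI computed from the recorded pair.

Disease: per exam one categorical draw — diabetes with probability
p_d = clamp(base_d(age)·RR_d^obese), else pre-diabetes with
p_p = clamp(base_p(age)·RR_p^obese, ≤ 1 − p_d) — which makes the
configured prevalence ratios exact by construction; hypertension drawn
independently the same way.  Base prevalences rise linearly with age past
40 (pre-diabetes 0.05 + 0.004/yr, diabetes 0.01 + 0.002/yr, hypertension
0.10 + 0.008/yr); risk ratios 2.8/2.4 (pre-diabetes F/M), 3.5/2.8
(diabetes), 1.5/1.8 (hypertension).  Risk is tied to *true* obesity, which
is what lets the corrected-BMI RR exceed the current-BMI RR in the
analysis.  Glucose and blood pressure are then drawn uniformly from ranges
consistent with the drawn state (normal glucose U(70, 140], pre-diabetic
U(140, 200], diabetic U(200, 300]; half of hypertensive exams are coded as
medicated and may have sub-threshold pressures, exercising the OR in the
hypertension definition).  The marginal glucose/BP distributions are
calibration conveniences, not population estimates.

What the generator does *not* model: birth-cohort height effects,
mortality and dropout, skewed or age-varying BMI variance, correlated
measurement errors, medication effects on glucose, non-biennial visit
schedules.  Passing recovery tests therefore demonstrates the estimators
are consistent under the stated data-generating process, not that real
cohort estimates would be unbiased.

## Numerical choices and edge cases

- Heights cm, weights kg, ages decimal years internally; imperial rounding
  exists only inside the measurement model (2.54 cm/in, 0.45359237 kg/lb).
- LOWESS on a constant or exactly linear series is the identity to
  numerical tolerance; a degree-1 local fit at the age-40 kink of a
  hockey-stick trajectory is slightly biased (≲ 0.3 cm for default
  parameters), which bounds the accuracy of young-height recovery under
  nonzero shrinkage.
- Age bins use `width·round(age/width)`; ties at bin edges have measure
  zero for continuous ages.  Within a bin the exam closest to the centre
  wins; exact ties resolve to the younger exam.
- Determinism: one `numpy` Generator seeded from the config; identical
  config ⇒ byte-identical CSV outputs.

## Known limitations

- The degree-1 shrinkage trend is fit through both the flat pre-40 segment
  and the post-40 linear decline.  A straight line through that
  hockey-stick shape attenuates the slope by ≈ 6–8% under the default
  design (enrollment 30–38, exams to 80), so the fitted 40→80 loss
  under-reports the generator's true mean loss (≈ 4.44 cm fitted vs 4.8 cm
  true for women; the quadratic fit reduces the gap).  This is a property
  of the estimator, deliberately kept as specified; the truth table lets
  users measure it directly.
- Misclassification levels are strongly calibration-dependent: they move
  with the BMI distribution near the 25/30 cutoffs (young-BMI mean/sd and
  the post-40 BMI drift) as much as with height loss itself.
- The RR is a crude prevalence ratio per bin; no adjustment, weighting or
  survival structure.  Confidence intervals are plotting aids only.
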