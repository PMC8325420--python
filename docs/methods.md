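# Methods

`trialmon` implements central statistical monitoring of a multicentre
randomised trial: data-completeness tracking, protocol
quality-deficiency indicators, and multivariate centre-anomaly
detection with Monte-Carlo resampling, all feeding blinded markdown
reports and an append-only decision log.  This note records the models,
the defaults and why, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Completeness

Each participant × data-entry module carries a due date, an optional
completion date and a completed flag.  At a reporting date each cell is
`complete`, `pending` (due date strictly in the future) or `overdue`.
Centre-level completion proportions are `n_complete / n_due` where
`n_due` counts complete + overdue cells: entries not yet owed are kept
out of the denominator, since a denominator of "all participants due"
is the only one under which a centre can reach 1.0 at any time.
Consent-withdrawn or declined participants leave the denominators
entirely (policy switch `exclude_withdrawn`, default on): the model
stores no withdrawal date, so partial credit for modules completed
before withdrawal is not attempted.  Days overdue are whole calendar
days relative to the reporting date.

## Quality-deficiency indicators

Seven protocol-adherence proportions with definition-specific
denominators (see `trialmon.quality` for the exact predicates).
Survival conditions are strict: "alive after 35 days" excludes a death
at exactly day 35, "alive after 72 h" a death at exactly 72 h.
Late initiation of cerebral oximetry means a start strictly later than
6 h from birth; the 0–6 h window is compliant.

Two deliberate design choices:

- **Indicator 2's denominator** is the set of participants with a
  recorded oximetry start time (the monitored set) rather than the
  experimental arm looked up by allocation.  Per protocol the two sets
  coincide, and this keeps every indicator except #7 computable — and
  unchanged — when the restricted allocation field is withheld.
- **Indicators 5 and 6** are read literally as proportions over all
  participants with the diagnosis variable recorded (numerator:
  diagnosis present and scan absent), not over diagnosed participants
  only.

Indicator 7 (control-arm participants monitored unblinded) is the only
computation in the package entitled to read the restricted allocation
field.  Indicator reporting has no small-centre floor; only the anomaly
analysis and report *presentation* exclude small centres.

The follow-up window check computes, per participant, the day they
reach 36+0 weeks postmenstrual age — birth date + (252 −
gestational-age-at-birth) days — and flags a follow-up assessment dated
strictly later.  Equality passes, matching an entry system that forbids
dates *later than* 36+0 weeks PMA.  The 36-week module's completion
date doubles as the assessment date, because the variable dictionary
has no date-valued kind; the generator draws clean assessments in the
0–3 days before the PMA day.

## Centre-anomaly detection

Centres are points in feature space: each monitored continuous
variable contributes the centre mean, each binary variable the centre
proportion of its event level (categoricals expand to per-level
indicators).  Exclusion rules come first: centres with fewer than
`min_participants_per_centre` (default 5) participants are excluded,
and a feature is dropped when *any* included centre has fewer than
`min_entries_per_variable` (default 5) entries of it — applied
globally so all centres share one feature space.  Residual missing
values are mean-imputed within centre (monitoring-grade, not
inference-grade).  Fewer than three included centres is an error: a
distance to a common mean of two points is meaningless.

Features are standardised to zero mean and unit variance across
centres (scale = across-centre SD, ddof 1), putting proportions and
means on one scale; zero-variance features are dropped with a logged
reason.  The covariance `S` of the standardised centre vectors is
shrunk towards its diagonal,

    Sigma* = (1 - lambda) S + lambda diag(S),

with `lambda` either fixed in [0, 1] or `"auto"`, which uses the
Ledoit–Wolf shrinkage intensity (its target coincides with `diag(S) =
I` on the standardised scale).  The intensity grows with p/n and keeps
`Sigma*` well conditioned even when the panel is wider than the number
of centres — a condition-number criterion alone picks shrinkage that is
far too small in that regime and inflates distances in the null space
of `S` until every centre looks anomalous.  At `lambda = 1` distances
reduce to the quadrature sum of per-feature z-scores.

The centre distance is `d = sqrt((x - mu)' Sigma*^{-1} (x - mu))`,
computed by Cholesky triangular solves.

**The 2-SD limit.**  A scalar threshold `t` (default 2) cannot be
compared directly with a p-dimensional distance: under the reference
normal the typical clean centre sits at `d ≈ sqrt(p)`, so at p = 6 a
raw cut at 2 would flag almost everyone.  The limit is therefore the
radius of the probability contour holding the same mass as the
two-sided ±t-SD interval in one dimension,

    r(t, p) = sqrt(chi2_p^{-1}(2 Phi(t) - 1)),

which equals `t` exactly at p = 1 (3.58 at t = 2, p = 6).  "Outside 2
standard deviations" then means the same thing whatever the panel size.

**Resampling.**  For each included centre its own participants are
resampled with replacement (sample size = centre size), the summary
vector recomputed, standardised with the *fixed* common model, and the
distance taken; 10,000 resamples by default.  Holding the model fixed
means the distribution quantifies only the centre's own sampling
error.  Flag tiers: *suspected* when the median resampled distance
exceeds the radius (worth discussing), *confirmed* when even the 5%
quantile does (outside the limit after allowing for sampling error).
The whole pipeline is deterministic under its seed.

**Finite-centre calibration.**  With the common mean and covariance
estimated from the same n centres, the null law of `d^2 n/(n-1)^2` is
Beta(p/2, (n-p-1)/2) exactly (Gaussian exchangeable centres), so the
chi-square reference is mildly conservative at monitoring scale: at
n = 30, p = 6 the exceedance of the chi-square 2-SD-equivalent quantile
is 0.0185 rather than the nominal 0.0455.  The calibration experiment
pools 10 replicate trials (300 centres) so its 3-SE binomial band
(±0.036) is read against this known O(1/n) bias; it is a check of
approximate, not exact, calibration.

**A caveat on the suspected tier.**  Bootstrap noise adds roughly one
across-centre variance per feature to the resampled squared distance.
In the synthetic null — perfectly exchangeable centres, where
across-centre spread *equals* within-centre sampling error — the
median resampled distance therefore sits above the observed one, and
the suspected tier fires liberally, increasingly so as the panel
widens.  In real multicentre data genuine centre heterogeneity makes
the across-centre scale larger than the bootstrap noise and the effect
fades.  The confirmed tier is the operative decision rule; suspected is
a discussion prompt.

## Blinded reporting and the log

Centre acronyms are 4-letter uppercase codes sampled without
replacement from the 26^4 space under a fixed seed; a candidate
sharing a 3+-letter substring with its centre id is rejected.  All four
rendered documents are blinded — centre ids become acronyms and
participant ids become within-centre ordinals; a centre missing from
the blinding map raises rather than falling back to the raw id.  The
unblinded operational artifact is the overdue contact list CSV, which
is not a rendered report.  The full quality report places per-variable
centre-stratified summaries before a clearly separated Mahalanobis
section, supporting the two-pass review (first unaided, then with the
distances).  Rendering is pure string construction over the input
tables, hence byte-reproducible.

The decision log is JSON-lines and append-only; a correction is a new
entry for the same flag id, and the latest entry per flag carries the
current resolution.  Summary counts (flagged, contacted, corrected and
their rounded percentage shares) are always recomputed by folding over
the log.

## Synthetic data generator

The generator emulates an extremely-preterm multicentre trial at
monitoring time: 20 centres × 20 participants by default (configurable
up to the 70-centre scale), gestational ages uniform on 154–195 days,
balanced within-centre allocation, a 12% death rate with exponential
death times (mean 25 days), 2% consent withdrawal, enrolment spread
over 540 days before the snapshot, and a 31-variable monitored panel
(12 continuous, 19 binary) spanning participant characteristics,
intervention process, quality measures and outcomes.  Module entries
(baseline, intervention, 72 h, 36-week follow-up) fall due at fixed
offsets from birth — the follow-up at the individual PMA-36 day — and
completion lags are geometric (p = 0.5 per day), giving realistic
overdue tails.  Clean centres are exchangeable draws from one common
distribution: any apparent centre effect in clean data is sampling
noise by construction.

Planted anomalies mirror the deviation taxonomy: unit-scale clerical
outliers (value × factor), centre-wide systematic shifts in pooled-SD
units or level swaps (misunderstandings), fabricated data as a
variance shrink plus rounding to a coarse grid (natural variance is
hard to fake), control-arm unblinded-monitoring violations, follow-up
assessments pushed past the PMA-36 day, and missingness bursts that
blank a module.  Every touched record is logged to a separate
ground-truth JSON-lines file never embedded in the dataset.

What the generator does *not* emulate: treatment effects, realistic
outcome correlations (variables are independent given the centre),
centre-level case-mix heterogeneity, informative missingness, or
date-entry idiosyncrasies (decimal markers, 12/24-h clocks).  Passing
the validation battery therefore demonstrates correctness of the
machinery and its operating characteristics under exchangeability —
not field performance on heterogeneous real centres, where the
across-centre scale absorbs genuine heterogeneity as described above.

## Experiment sizes

The validation battery uses: 1,000 random instances (p ≤ 8) for the
distance oracle; 10 replicates of 30 centres × 40 participants × 6
continuous features for null calibration; 100 replicates of 20 × 20 ×
6 for the power study (a 4-SD centre-wide shift on one feature,
10,000 resamples, with matched clean replicates for specificity); 50
randomised 5-centre trials for the blinding sweep; and a 6-centre
end-to-end double run for byte determinism.  The 6-feature experiment
panel keeps the planted single-feature shift identifiable at 20
centres; at p = 31 > n the joint distance dilutes a one-feature signal
below any sensible limit, which is a property of the statistic, not of
the implementation.
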