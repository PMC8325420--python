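# trialmon

Central statistical monitoring for multicentre randomised clinical
trials: who hasn't entered their data, where the protocol is slipping,
and which centres look statistically unlike the rest — computed from
a plain-CSV snapshot, rendered as blinded reports, and validated
end-to-end on synthetic trials with planted anomalies.

Built for the coordinating team of a trial (trial manager,
statistician, clinician) who review accumulating data centrally
instead of relying on on-site source verification.  The package covers
three monitoring outcomes:

- **Completeness** — per participant × data-entry module: due date,
  completion date, status; centre-level completion proportions
  (numerator: participants with complete entries, denominator:
  participants due), and an overdue contact list.
- **Quality** — seven protocol quality-deficiency indicators with
  survival-conditioned denominators (e.g. missing cranial ultrasound
  scans among infants alive after day 35; unblinded cerebral oximetry
  in the control arm), plus a 36+0-weeks-postmenstrual-age follow-up
  window check.
- **Deviations** — centre-level anomaly detection for suspected
  outliers, misunderstandings and fabricated data.

## The statistic

Each centre *i* is summarised by a vector x_i over the monitored
variable panel (means for continuous variables, proportions for binary
ones), standardised across centres.  With common mean μ and shrunk
covariance Σ* = (1−λ)S + λ·diag(S) (λ from Ledoit–Wolf by default),
the centre's Mahalanobis distance is

    d_i = sqrt((x_i − μ)ᵀ Σ*⁻¹ (x_i − μ))   [SD units]

Its sampling error is quantified by bootstrap: the centre's own
participants are resampled 10,000 times, each resample re-summarised
and measured against the fixed common model.  A centre is *suspected*
when the median resampled distance lies outside the 2-SD limit and
*confirmed* when even the 5% quantile does.  The scalar limit is
converted to the p-dimensional radius enclosing the same probability
mass as ±2 SD in one dimension, so the rule is panel-size invariant.
Centres with fewer than 5 participants are excluded; variables with
fewer than 5 entries at any included centre are dropped.  The analysis
never reads group allocation, and reports replace centre identities
with seeded random acronyms.

See `docs/methods.md` for the full model description and
`docs/schema.md` for the CSV interchange format.

## Worked example

```python
from trialmon import (AnomalySpec, MonitoringConfig, SynthConfig,
                      detect, generate_trial, inject_anomalies)
from trialmon.synthgen import continuous_panel

cfg = SynthConfig(n_centres=20, participants_per_centre=20,
                  variable_panel=continuous_panel(6), rng_seed=7)
clean, _ = generate_trial(cfg)

# plant a centre-wide systematic error: +4 SD on one variable at C13
tampered, truth = inject_anomalies(
    clean, [AnomalySpec("misunderstanding", "C13", "score_04",
                        magnitude=4.0, affected_fraction=1.0)], seed=7)

result = detect(tampered, MonitoringConfig(rng_seed=7))
for flag in result.flags:
    if flag.tier != "none":
        print(f"{flag.centre_id}: observed d = {flag.observed:.2f}, "
              f"5% quantile = {flag.q05_resampled:.2f}, "
              f"limit radius = {flag.radius:.2f} -> {flag.tier}")
```

prints

```
C02: observed d = 3.16, 5% quantile = 2.42, limit radius = 3.58 -> suspected
C13: observed d = 4.76, 5% quantile = 4.40, limit radius = 3.58 -> confirmed
C15: observed d = 3.09, 5% quantile = 2.22, limit radius = 3.58 -> suspected
```

The planted centre C13 is the only one *confirmed*: even after
allowing for its own sampling error it sits outside the 2-SD limit
(radius 3.58 for a 6-variable panel).  The two *suspected* centres are
discussion prompts — their observed distances are inside the limit and
only the resampling noise pushes their medians past it, the expected
behaviour on perfectly exchangeable synthetic centres
(`docs/methods.md` discusses this).

The same snapshot flows through the rest of the pipeline:
`compute_completeness` / `summarise_completeness` (a centre with 17 of
20 follow-ups complete reports 17/20 = 0.85), `summarise_quality` for
the indicator panel, and `render_reports` for the four blinded
markdown documents.  Everything is also reachable from the CLI:

```
trialmon synth --out data --seed 11
trialmon completeness --data data --out comp
trialmon quality      --data data --out qual
trialmon detect       --data data --out det --seed 11
trialmon report       --data data --out rep --seed 11
trialmon log add      --log log.jsonl --meeting m1 --flag-id F001 \
    --centre QXZP --item birth_weight_g --decision contact_investigator
```

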