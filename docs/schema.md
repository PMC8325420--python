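# Interchange schema

One monitoring snapshot is four flat CSV files (UTF-8, comma-separated,
header row required) plus an optional `snapshot.json` sidecar carrying
the snapshot date.  Dates are `YYYY-MM-DD`; timestamps are
`YYYY-MM-DD HH:MM` (minutes precision, single-timezone assumption);
booleans are the strings `true` / `false`; missing fields are empty.
The same schema is available machine-readably as `trialmon.SCHEMA`
(`trialmon.trial_model.dump_schema` writes it as JSON).

## participants.csv

| column | type | notes |
|---|---|---|
| participant_id | string | unique |
| centre_id | string | |
| birth_datetime | timestamp | |
| gestational_age_days | integer | at birth; extremely-preterm window 154–195 by default |
| randomisation_datetime | timestamp | ≥ birth_datetime |
| allocation | `experimental` / `control` | **restricted** — loaded into a field that only the control-arm quality indicator may read |
| death_datetime | timestamp or empty | ≥ birth_datetime |
| consent_status | `consented` / `withdrawn` / `declined` | |

## entries.csv

One row per participant × data-entry module; `(participant_id,
module_name)` unique.

| column | type | notes |
|---|---|---|
| participant_id | string | must exist in participants.csv |
| module_name | string | e.g. `baseline`, `intervention`, `72h`, `36week_followup` |
| due_date | date | |
| completion_date | date or empty | required when completed; for the 36-week module this is the assessment date |
| completed | boolean | |

## values.csv

Long format; a missing value is an absent row.

| column | type | notes |
|---|---|---|
| participant_id | string | must exist in participants.csv |
| variable_name | string | must exist in dictionary.csv |
| value | number or level code | numeric for continuous variables |

## dictionary.csv

| column | type | notes |
|---|---|---|
| name | string | unique |
| kind | `continuous` / `binary` / `categorical` | |
| unit | string or empty | continuous only |
| range_min, range_max | number or empty | continuous only, min < max |
| levels | `|`-separated codes | binary: exactly 2, the second is the event level |
| monitored | boolean | member of the deviation-monitoring panel |

Referential violations (unknown participant or variable, duplicate
keys) are rejected at load with addressed messages; value-level
implausibilities (out-of-range values, chronology errors) are *loaded*
and surfaced as findings, because the monitoring workflow's job is to
detect, contact and correct — not silently clean.
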