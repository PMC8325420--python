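"""Data-completeness monitoring.

One cell per participant x data-entry module records the due date, the
actual completion date and a status: complete, pending (not yet due), or
overdue.  Centre-level completion proportions use participants-due as
the denominator and participants-complete as the numerator — e.g. 17
completed of 20 due gives 0.85 — with not-yet-due entries excluded.
Missing data is pursued to zero tolerance, so the overdue contact list
is exact, sorted for triage (worst first within each centre).
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .trial_model import MonitoringConfig, TrialDataset

STATUSES = ("complete", "pending", "overdue")

CELL_COLUMNS = ["participant_id", "centre_id", "module_name", "due_date",
                "completion_date", "status"]


def compute_completeness(dataset: TrialDataset, as_of: date,
                         config: MonitoringConfig | None = None
                         ) -> pd.DataFrame:
    """One row per (participant, module) entry with its status at ``as_of``.

    Participants whose consent was withdrawn or declined are excluded
    (policy switch ``exclude_withdrawn``, default on): no further data
    entry can be expected of them, so they must not inflate denominators.
    """
    config = config or MonitoringConfig()
    as_of_ts = pd.Timestamp(as_of)
    p = dataset.participants[["participant_id", "centre_id", "consent_status"]]
    cells = dataset.entries.merge(p, on="participant_id", how="left")
    if config.exclude_withdrawn:
        cells = cells[cells["consent_status"] == "consented"]
    status = np.where(
        cells["completed"], "complete",
        np.where(cells["due_date"] < as_of_ts, "overdue", "pending"))
    cells = cells.assign(status=status)
    return (cells[CELL_COLUMNS]
            .sort_values(["centre_id", "participant_id", "module_name"],
                         kind="stable")
            .reset_index(drop=True))


def summarise_completeness(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-(centre, module) completion proportions plus overall rows.

    ``n_due`` counts complete + overdue cells (pending entries are not
    yet owed); ``proportion`` is NaN when nothing is due.  The overall
    row per module pools all centres under centre_id "ALL".
    """
    due = cells[cells["status"] != "pending"]

    def agg(group_cols: list[str], frame: pd.DataFrame) -> pd.DataFrame:
        g = frame.groupby(group_cols, sort=True)
        out = g.agg(
            n_complete=("status", lambda s: int((s == "complete").sum())),
            n_due=("status", "size")).reset_index()
        return out

    per_centre = agg(["centre_id", "module_name"], due)
    overall = agg(["module_name"], due)
    overall.insert(0, "centre_id", "ALL")
    # modules with nothing due still appear, with an empty denominator
    all_modules = cells[["centre_id", "module_name"]].drop_duplicates()
    per_centre = all_modules.merge(per_centre, how="left",
                                   on=["centre_id", "module_name"])
    table = pd.concat([per_centre, overall], ignore_index=True)
    for col in ("n_complete", "n_due"):
        table[col] = pd.to_numeric(table[col]).fillna(0).astype(int)
    table["proportion"] = np.where(
        table["n_due"] > 0, table["n_complete"] / table["n_due"].replace(0, 1),
        np.nan)
    return (table.sort_values(["centre_id", "module_name"], kind="stable")
            .reset_index(drop=True))


def list_overdue(cells: pd.DataFrame, as_of: date) -> pd.DataFrame:
    """Contact list of overdue entries: centre, participant, module,
    whole days overdue; sorted by centre, then most-overdue first."""
    od = cells[cells["status"] == "overdue"].copy()
    od["days_overdue"] = (pd.Timestamp(as_of) - od["due_date"]).dt.days
    od = od[["centre_id", "participant_id", "module_name", "days_overdue"]]
    return (od.sort_values(["centre_id", "days_overdue", "participant_id"],
                           ascending=[True, False, True], kind="stable")
            .reset_index(drop=True))
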