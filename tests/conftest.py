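from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from trialmon import TrialDataset, VariableDef

BINARY = dict(kind="binary", levels=("no", "yes"))


def make_dictionary() -> list[VariableDef]:
    return [
        VariableDef("early_scan", **BINARY, monitored=True),
        VariableDef("late_scan", **BINARY, monitored=True),
        VariableDef("oximetry_start_hours", "continuous", unit="h",
                    allowed_range=(0, 72), monitored=True),
        VariableDef("oximetry_stopped_early", **BINARY, monitored=True),
        VariableDef("severe_brain_injury", **BINARY, monitored=True),
        VariableDef("phvd_or_atrophy", **BINARY, monitored=True),
        VariableDef("unblinded_oximetry", **BINARY, monitored=True),
    ]


def build_dataset(parts: list[dict], entries: list[dict] | None = None,
                  values: list[tuple] | None = None,
                  dictionary: list[VariableDef] | None = None,
                  snapshot: str = "2021-06-01",
                  allocation: dict[str, str] | None = None) -> TrialDataset:
    """Hand-built snapshot; every participant dict may omit defaults."""
    rows = []
    for i, p in enumerate(parts):
        birth = pd.Timestamp(p.get("birth", "2021-01-01 08:00"))
        death = p.get("death_days")
        rows.append({
            "participant_id": p.get("pid", f"P{i + 1:02d}"),
            "centre_id": p.get("centre", "C01"),
            "birth_datetime": birth,
            "gestational_age_days": p.get("ga", 180),
            "randomisation_datetime": birth + pd.Timedelta(hours=6),
            "death_datetime": (birth + pd.Timedelta(days=death)
                               if death is not None else pd.NaT),
            "consent_status": p.get("consent", "consented"),
        })
    columns = ["participant_id", "centre_id", "birth_datetime",
               "gestational_age_days", "randomisation_datetime",
               "death_datetime", "consent_status"]
    participants = pd.DataFrame(rows, columns=columns)
    participants["gestational_age_days"] = (
        participants["gestational_age_days"].astype("Int64"))
    for col in ("birth_datetime", "randomisation_datetime",
                "death_datetime"):
        participants[col] = pd.to_datetime(participants[col])

    edf = pd.DataFrame(entries or [], columns=[
        "participant_id", "module_name", "due_date", "completion_date",
        "completed"])
    if len(edf):
        edf["due_date"] = pd.to_datetime(edf["due_date"])
        edf["completion_date"] = pd.to_datetime(edf["completion_date"])
        edf["completed"] = edf["completed"].astype(bool)
    else:
        edf = edf.astype({"due_date": "datetime64[ns]",
                          "completion_date": "datetime64[ns]",
                          "completed": bool})

    vdf = pd.DataFrame(values or [], columns=[
        "participant_id", "variable_name", "value"])
    vdf["value"] = vdf["value"].astype(object)

    alloc = None
    if allocation is not None:
        alloc = pd.Series(allocation, name="allocation")
    return TrialDataset(participants, edf, vdf,
                        dictionary if dictionary is not None
                        else make_dictionary(),
                        dt.date.fromisoformat(snapshot), alloc)


@pytest.fixture
def scan_cohort() -> TrialDataset:
    """One centre, 10 infants: 2 die on/before day 35, and of the 8
    survivors 3 lack both cranial ultrasound scans."""
    parts, values, alloc = [], [], {}
    for i in range(1, 11):
        pid = f"P{i:02d}"
        death = {9: 10, 10: 35}.get(i)   # day-35 death is a boundary case
        parts.append({"pid": pid, "death_days": death})
        alloc[pid] = "experimental" if i % 2 else "control"
        scans = "no" if i <= 3 else "yes"
        values += [(pid, "early_scan", scans), (pid, "late_scan", scans)]
        values += [(pid, "severe_brain_injury", "no"),
                   (pid, "phvd_or_atrophy", "no")]
        if i % 2:   # monitored (experimental) arm
            values += [(pid, "oximetry_start_hours", 3.0),
                       (pid, "oximetry_stopped_early", "no")]
        else:
            values += [(pid, "unblinded_oximetry", "no")]
    return build_dataset(parts, values=values, allocation=alloc)
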