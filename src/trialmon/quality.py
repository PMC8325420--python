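"""Protocol quality-deficiency indicators and the follow-up-window check.

Seven indicators, each a proportion with a definition-specific
denominator, several conditioned on survival:

1. no early AND no late cranial ultrasound scan, among participants
   alive after 35 days of life;
2. late initiation of cerebral oximetry (start > 6 h from birth), among
   participants with a recorded oximetry start time (the monitored set);
3. oximetry stopped prematurely, among monitored participants alive
   after 72 h of life;
4. consent withdrawn or declined, among all participants;
5. severe brain injury but no cranial ultrasound scan at all;
6. post-haemorrhagic ventricular dilatation or cerebral atrophy but no
   late scan;
7. unblinded cerebral oximetry monitoring, among control-arm
   participants — the only computation entitled to read the restricted
   allocation field.

"Alive after 35 days" and "alive after 72 h" are strict: a death exactly
on the boundary leaves the denominator.

The follow-up-window check flags every participant whose 36-week
assessment was dated strictly later than the day they reached 36+0
weeks postmenstrual age (252 days PMA); a date exactly on the boundary
is compliant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError
from .trial_model import Finding, MonitoringConfig, TrialDataset

INDICATOR_DESCRIPTIONS = {
    1: "no early and no late cranial ultrasound scan (alive after 35 days)",
    2: "late initiation of cerebral oximetry monitoring (> 6 h from birth)",
    3: "cerebral oximetry stopped prematurely (alive after 72 h)",
    4: "consent withdrawn or declined",
    5: "severe brain injury but no cranial ultrasound scan",
    6: "PHVD or cerebral atrophy but no late cranial ultrasound scan",
    7: "control-group participants with unblinded cerebral oximetry",
}

#: default mapping from indicator source roles to dictionary variables
DEFAULT_VARIABLE_MAP = {
    "early_scan": "early_scan",
    "late_scan": "late_scan",
    "oximetry_start_hours": "oximetry_start_hours",
    "oximetry_stopped_early": "oximetry_stopped_early",
    "severe_brain_injury": "severe_brain_injury",
    "phvd_or_atrophy": "phvd_or_atrophy",
    "unblinded_oximetry": "unblinded_oximetry",
}

LATE_OXIMETRY_HOURS = 6.0


@dataclass(frozen=True)
class IndicatorResult:
    indicator_id: int
    centre_id: str            # a centre, or "ALL" for the pooled row
    numerator: int
    denominator: int

    @property
    def proportion(self) -> float:
        return (self.numerator / self.denominator if self.denominator
                else float("nan"))


@dataclass(frozen=True)
class FollowupWindowFlag:
    participant_id: str
    followup_date: date
    pma36_date: date
    days_late: int            # strictly positive by construction


@dataclass
class QualitySummary:
    indicators: pd.DataFrame
    followup_flags: list[FollowupWindowFlag]
    followup_findings: list[Finding] = field(default_factory=list)


def _mapped(config: MonitoringConfig, role: str, dataset: TrialDataset,
            indicator_id: int) -> str:
    name = {**DEFAULT_VARIABLE_MAP, **config.variable_map}[role]
    if name not in dataset.variable_names:
        raise ConfigError(
            f"indicator {indicator_id}: variable {name!r} (role {role}) "
            "is not in the dictionary")
    return name


def _frame(dataset: TrialDataset) -> pd.DataFrame:
    """Participants joined with the wide value table."""
    wide = dataset.wide_values()
    return dataset.participants.merge(
        wide, left_on="participant_id", right_index=True, how="left")


def _alive_after(df: pd.DataFrame, delta: pd.Timedelta) -> pd.Series:
    survived = df["death_datetime"].isna()
    return survived | (df["death_datetime"] > df["birth_datetime"] + delta)


def _is(df: pd.DataFrame, col: str, level: str) -> pd.Series:
    if col not in df.columns:
        return pd.Series(False, index=df.index)
    return df[col] == level


def _has(df: pd.DataFrame, col: str) -> pd.Series:
    if col not in df.columns:
        return pd.Series(False, index=df.index)
    return df[col].notna()


def compute_indicator(dataset: TrialDataset, indicator_id: int,
                      config: MonitoringConfig | None = None
                      ) -> list[IndicatorResult]:
    """One result per centre plus a pooled "ALL" row.

    Participants missing a source variable needed to classify them are
    left out of both numerator and denominator.  There is no
    5-participant floor here: indicator reporting covers every centre
    (only the anomaly analysis excludes small centres).
    """
    config = config or MonitoringConfig()
    if indicator_id not in INDICATOR_DESCRIPTIONS:
        raise ConfigError(f"unknown indicator id {indicator_id}")
    df = _frame(dataset)

    if indicator_id == 1:
        early = _mapped(config, "early_scan", dataset, 1)
        late = _mapped(config, "late_scan", dataset, 1)
        denom = (_alive_after(df, pd.Timedelta(days=35))
                 & _has(df, early) & _has(df, late))
        numer = denom & _is(df, early, "no") & _is(df, late, "no")
    elif indicator_id == 2:
        start = _mapped(config, "oximetry_start_hours", dataset, 2)
        denom = _has(df, start)
        hours = pd.to_numeric(df.get(start), errors="coerce")
        numer = denom & (hours > LATE_OXIMETRY_HOURS)
    elif indicator_id == 3:
        stopped = _mapped(config, "oximetry_stopped_early", dataset, 3)
        denom = _alive_after(df, pd.Timedelta(hours=72)) & _has(df, stopped)
        numer = denom & _is(df, stopped, "yes")
    elif indicator_id == 4:
        denom = pd.Series(True, index=df.index)
        numer = df["consent_status"].isin(["withdrawn", "declined"])
    elif indicator_id == 5:
        injury = _mapped(config, "severe_brain_injury", dataset, 5)
        early = _mapped(config, "early_scan", dataset, 5)
        late = _mapped(config, "late_scan", dataset, 5)
        denom = _has(df, injury) & _has(df, early) & _has(df, late)
        numer = (denom & _is(df, injury, "yes")
                 & _is(df, early, "no") & _is(df, late, "no"))
    elif indicator_id == 6:
        phvd = _mapped(config, "phvd_or_atrophy", dataset, 6)
        late = _mapped(config, "late_scan", dataset, 6)
        denom = _has(df, phvd) & _has(df, late)
        numer = denom & _is(df, phvd, "yes") & _is(df, late, "no")
    else:  # indicator 7 — the only reader of the restricted allocation
        unblinded = _mapped(config, "unblinded_oximetry", dataset, 7)
        if not dataset.has_allocation():
            raise IntegrityError(
                "indicator 7 needs the restricted allocation field")
        alloc = df["participant_id"].map(dataset.restricted_allocation())
        denom = alloc == "control"
        numer = denom & _is(df, unblinded, "yes")

    results = []
    for centre, grp in df.groupby("centre_id", sort=True):
        results.append(IndicatorResult(
            indicator_id, str(centre),
            int(numer[grp.index].sum()), int(denom[grp.index].sum())))
    results.append(IndicatorResult(
        indicator_id, "ALL", int(numer.sum()), int(denom.sum())))
    return results


def check_followup_window(dataset: TrialDataset,
                          config: MonitoringConfig | None = None
                          ) -> tuple[list[FollowupWindowFlag], list[Finding]]:
    """Flag follow-up assessments dated after the 36+0-week PMA day.

    pma36_date = birth date + (252 - gestational age at birth) days.
    Equality is compliant; the flag requires a strictly later date.
    A missing gestational age yields a finding, never an exception.
    """
    config = config or MonitoringConfig()
    flags: list[FollowupWindowFlag] = []
    findings: list[Finding] = []
    entries = dataset.entries
    fup = entries[(entries["module_name"] == config.followup_module)
                  & entries["completion_date"].notna()]
    p = dataset.participants.set_index("participant_id")
    for _, row in fup.iterrows():
        pid = row["participant_id"]
        ga = p.loc[pid, "gestational_age_days"]
        if pd.isna(ga):
            findings.append(Finding(pid, "gestational_age_days", "ga_window",
                                    "error",
                                    "missing gestational age; follow-up "
                                    "window cannot be checked"))
            continue
        pma36 = (p.loc[pid, "birth_datetime"].normalize()
                 + pd.Timedelta(days=int(config.followup_pma_days - ga)))
        late = (row["completion_date"].normalize() - pma36).days
        if late > 0:
            flags.append(FollowupWindowFlag(
                pid, row["completion_date"].date(), pma36.date(), int(late)))
    flags.sort(key=lambda f: (-f.days_late, f.participant_id))
    return flags, findings


def summarise_quality(dataset: TrialDataset,
                      config: MonitoringConfig | None = None
                      ) -> QualitySummary:
    """All computable indicators per centre and overall, plus follow-up
    window flags; ordered by indicator then centre.

    Indicator 7 is skipped when the restricted allocation field was
    withheld — every other indicator is unaffected by the withholding.
    """
    config = config or MonitoringConfig()
    ids = [i for i in sorted(INDICATOR_DESCRIPTIONS)
           if i != 7 or dataset.has_allocation()]
    rows = []
    for i in ids:
        if dataset.participants.empty:
            continue
        for r in compute_indicator(dataset, i, config):
            rows.append((r.indicator_id, r.centre_id, r.numerator,
                         r.denominator, r.proportion))
    indicators = pd.DataFrame(rows, columns=[
        "indicator_id", "centre_id", "numerator", "denominator", "proportion"])
    flags, findings = check_followup_window(dataset, config)
    return QualitySummary(indicators, flags, findings)
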