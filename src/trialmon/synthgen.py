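"""Synthetic multicentre-trial generator with plantable anomalies.

Emulates a preterm-infant randomised trial at monitoring time: 20-70
centres, a 31-variable monitored panel (participant characteristics,
intervention, quality measures, outcomes), per-module data-entry
timelines, deaths, consent withdrawals, and missingness.  Clean centres
are exchangeable draws from one common distribution, so any detectable
centre effect in clean data is sampling noise by construction.

Anomalies of each deviation class — clerical outliers, centre-wide
misunderstandings, low-variance fabricated data, control-arm monitoring
violations, late follow-up assessment dates, and missingness bursts —
are injected on top of a clean snapshot, and every touched record is
written to a ground-truth log (a separate JSON-lines file, never part of
the dataset, so detectors cannot peek).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError
from .trial_model import (ALLOCATIONS, TrialDataset, VariableDef)

ANOMALY_KINDS = ("outlier", "misunderstanding", "fabrication",
                 "control_arm_monitoring", "late_followup",
                 "missingness_burst")


@dataclass(frozen=True)
class GenVariable:
    """A panel variable together with its generating parameters.

    ``arm`` restricts the variable to one randomisation arm (the
    cerebral-oximetry process variables exist only where the protocol
    mandates monitoring); ``None`` means collected for everyone.
    """

    definition: VariableDef
    mean: float | None = None          # continuous
    sd: float | None = None            # continuous
    p_event: float | None = None       # binary: probability of positive level
    arm: Literal["experimental", "control"] | None = None

    def __post_init__(self) -> None:
        if self.definition.kind == "continuous":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ConfigError(
                    f"{self.definition.name}: continuous needs mean and sd > 0")
        elif self.definition.kind == "binary":
            if self.p_event is None or not 0.0 <= self.p_event <= 1.0:
                raise ConfigError(
                    f"{self.definition.name}: binary needs p_event in [0,1]")


@dataclass(frozen=True)
class ModuleSpec:
    """A data-entry module and when it falls due.

    Either a fixed offset in days from birth, or — for the 36-week
    assessment — the day the infant reaches the configured postmenstrual
    age (birth + PMA - gestational age at birth).
    """

    name: str
    due_offset_days: int | None = None
    due_at_pma_days: int | None = None

    def __post_init__(self) -> None:
        if (self.due_offset_days is None) == (self.due_at_pma_days is None):
            raise ConfigError(
                f"module {self.name}: exactly one of due_offset_days / "
                "due_at_pma_days required")


def _cont(name, mean, sd, unit=None, rng=None, arm=None, monitored=True):
    return GenVariable(VariableDef(name, "continuous", unit=unit,
                                   allowed_range=rng, monitored=monitored),
                       mean=mean, sd=sd, arm=arm)


def _bin(name, p, arm=None, monitored=True):
    return GenVariable(VariableDef(name, "binary", levels=("no", "yes"),
                                   monitored=monitored), p_event=p, arm=arm)


def default_panel() -> list[GenVariable]:
    """The 31-variable monitored panel: 12 continuous, 19 binary.

    Parameter values are typical of an extremely-preterm cohort; they
    set the scale of the synthetic data, nothing more.
    """
    return [
        _cont("birth_weight_g", 850, 200, "g", (200, 2000)),
        _cont("oximetry_start_hours", 3.0, 1.5, "h", (0, 72),
              arm="experimental"),
        _cont("mean_rsto2_day1", 72, 6, "%", (0, 100), arm="experimental"),
        _cont("hours_below_hypoxic_threshold", 2.0, 1.8, "h", (0, 72),
              arm="experimental"),
        _cont("apgar_5min", 7.0, 2.0, "score", (0, 10)),
        _cont("cord_ph", 7.28, 0.08, "pH", (6.5, 7.8)),
        _cont("admission_temp_c", 36.4, 0.7, "degC", (30, 40)),
        _cont("days_mechanical_ventilation", 12, 8, "days", (0, 120)),
        _cont("days_to_full_enteral_feeds", 14, 6, "days", (0, 120)),
        _cont("weight_36wk_g", 2100, 350, "g", (500, 4500)),
        _cont("head_circumference_36wk_cm", 31.0, 1.5, "cm", (20, 45)),
        _cont("length_of_stay_days", 70, 20, "days", (0, 400)),
        _bin("early_scan", 0.96),
        _bin("late_scan", 0.93),
        _bin("oximetry_stopped_early", 0.05, arm="experimental"),
        _bin("unblinded_oximetry", 0.01, arm="control"),
        _bin("severe_brain_injury", 0.12),
        _bin("phvd_or_atrophy", 0.05),
        _bin("ivh_any", 0.25),
        _bin("bpd_36wk", 0.35),
        _bin("rop_treated", 0.08),
        _bin("nec_stage2plus", 0.07),
        _bin("sepsis_culture_positive", 0.20),
        _bin("pda_treated", 0.30),
        _bin("surfactant_given", 0.75),
        _bin("antenatal_steroids", 0.85),
        _bin("caesarean_delivery", 0.60),
        _bin("multiple_birth", 0.25),
        _bin("male_sex", 0.52),
        _bin("inotropes_first72h", 0.15),
        _bin("postnatal_steroids", 0.12),
    ]


def continuous_panel(n_features: int = 6) -> list[GenVariable]:
    """A plain continuous monitored panel for detection experiments."""
    return [_cont(f"score_{i + 1:02d}", 10.0 + i, 1.0 + 0.1 * i)
            for i in range(n_features)]


def default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec("baseline", due_offset_days=7),
        ModuleSpec("intervention", due_offset_days=10),
        ModuleSpec("72h", due_offset_days=10),
        ModuleSpec("36week_followup", due_at_pma_days=252),
    ]


@dataclass
class SynthConfig:
    """Conditions under which a synthetic snapshot is generated."""

    n_centres: int = 20
    participants_per_centre: int | Sequence[int] = 20
    variable_panel: list[GenVariable] = field(default_factory=default_panel)
    module_set: list[ModuleSpec] = field(default_factory=default_modules)
    missingness_rate: float = 0.02
    death_rate: float = 0.12
    withdrawal_rate: float = 0.02
    enrolment_days: int = 540
    snapshot_date: date = date(2021, 5, 24)
    completion_lag_p: float = 0.5    # geometric per-day completion hazard
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_centres < 2:
            raise ConfigError("n_centres must be >= 2")
        for rate in (self.missingness_rate, self.death_rate,
                     self.withdrawal_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("rates must be in [0,1]")
        if not 0.0 < self.completion_lag_p <= 1.0:
            raise ConfigError("completion_lag_p must be in (0,1]")
        names = [g.definition.name for g in self.variable_panel]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate variable names in panel")

    def per_centre(self) -> list[int]:
        if isinstance(self.participants_per_centre, int):
            return [self.participants_per_centre] * self.n_centres
        sizes = list(self.participants_per_centre)
        if len(sizes) != self.n_centres:
            raise ConfigError("per-centre list length must equal n_centres")
        return sizes


@dataclass(frozen=True)
class AnomalySpec:
    """One planted deviation.

    ``magnitude`` is kind-specific: unit-scale factor (outlier), shift in
    pooled-SD units (misunderstanding), variance multiplier < 1
    (fabrication), days late (late_followup); unused otherwise.
    ``target_variable`` names the affected variable, or the affected
    module for missingness bursts.
    """

    kind: str
    target_centre: str
    target_variable: str | None = None
    magnitude: float = 0.0
    affected_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise ConfigError(f"unknown anomaly kind {self.kind!r}")
        if not 0.0 < self.affected_fraction <= 1.0:
            raise ConfigError("affected_fraction must be in (0,1]")
        if self.kind == "fabrication" and not 0.0 < self.magnitude < 1.0:
            raise ConfigError("fabrication magnitude is a variance "
                              "multiplier in (0,1)")


@dataclass(frozen=True)
class PlantedAnomaly:
    spec: AnomalySpec
    participant_ids: tuple[str, ...]
    record_keys: tuple[tuple, ...]   # ("values", pid, var) / ("entries", pid, mod)


@dataclass
class GroundTruth:
    planted: list[PlantedAnomaly] = field(default_factory=list)

    def participant_ids(self, kind: str | None = None) -> set[str]:
        out: set[str] = set()
        for p in self.planted:
            if kind is None or p.spec.kind == kind:
                out.update(p.participant_ids)
        return out

    def record_keys(self) -> set[tuple]:
        out: set[tuple] = set()
        for p in self.planted:
            out.update(p.record_keys)
        return out

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.planted:
                fh.write(json.dumps({
                    "spec": dataclasses.asdict(p.spec),
                    "participant_ids": list(p.participant_ids),
                    "record_keys": [list(k) for k in p.record_keys],
                }) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "GroundTruth":
        planted = []
        for line in Path(path).read_text().splitlines():
            d = json.loads(line)
            planted.append(PlantedAnomaly(
                AnomalySpec(**d["spec"]), tuple(d["participant_ids"]),
                tuple(tuple(k) for k in d["record_keys"])))
        return cls(planted)


# --------------------------------------------------------------------------
# generation


def generate_trial(config: SynthConfig) -> tuple[TrialDataset, GroundTruth]:
    """Generate one clean snapshot; ground truth starts empty.

    Deterministic: identical config (including seed) reproduces a
    byte-identical dataset.
    """
    rng = np.random.default_rng(config.rng_seed)
    snapshot = pd.Timestamp(config.snapshot_date)
    sizes = config.per_centre()

    prows, alloc_pairs = [], []
    for c, n in enumerate(sizes):
        centre_id = f"C{c + 1:02d}"
        # balanced allocation within centre
        arms = np.array([ALLOCATIONS[i % 2] for i in range(n)])
        rng.shuffle(arms)
        for i in range(n):
            pid = f"{centre_id}-P{i + 1:03d}"
            birth = snapshot - pd.Timedelta(
                days=float(rng.uniform(7, config.enrolment_days)))
            birth = birth.floor("min")
            ga = int(rng.integers(154, 196))
            rand_dt = (birth + pd.Timedelta(hours=float(rng.uniform(1, 24)))
                       ).floor("min")
            death = pd.NaT
            if rng.random() < config.death_rate:
                death_day = float(np.clip(rng.exponential(25.0), 0.5, 120.0))
                death = (birth + pd.Timedelta(days=death_day)).floor("min")
            u = rng.random()
            consent = ("withdrawn" if u < config.withdrawal_rate * 0.75
                       else "declined" if u < config.withdrawal_rate
                       else "consented")
            prows.append((pid, centre_id, birth, ga, rand_dt, death, consent))
            alloc_pairs.append((pid, arms[i]))

    participants = pd.DataFrame(prows, columns=[
        "participant_id", "centre_id", "birth_datetime",
        "gestational_age_days", "randomisation_datetime", "death_datetime",
        "consent_status"])
    participants["gestational_age_days"] = (
        participants["gestational_age_days"].astype("Int64"))
    allocation = pd.Series(dict(alloc_pairs), name="allocation")
    allocation.index.name = None

    # module entries
    erows = []
    for _, p in participants.iterrows():
        birth_day = p["birth_datetime"].normalize()
        for mod in config.module_set:
            if mod.due_offset_days is not None:
                due = birth_day + pd.Timedelta(days=mod.due_offset_days)
                lag = int(rng.geometric(config.completion_lag_p)) - 1
                completion = due + pd.Timedelta(days=lag)
            else:
                due = birth_day + pd.Timedelta(
                    days=int(mod.due_at_pma_days - p["gestational_age_days"]))
                # assessment happens on or up to 3 days before the PMA date
                completion = due - pd.Timedelta(days=int(rng.integers(0, 4)))
            completed = completion <= snapshot
            erows.append((p["participant_id"], mod.name, due,
                          completion if completed else pd.NaT, completed))
    entries = pd.DataFrame(erows, columns=[
        "participant_id", "module_name", "due_date", "completion_date",
        "completed"])

    # variable values (long format; a missing value is an absent row)
    vrows = []
    arm_of = allocation
    for gv in config.variable_panel:
        d = gv.definition
        mask = np.ones(len(participants), dtype=bool)
        if gv.arm is not None:
            mask = (participants["participant_id"].map(arm_of) == gv.arm
                    ).to_numpy()
        idx = np.flatnonzero(mask)
        if d.kind == "continuous":
            vals = rng.normal(gv.mean, gv.sd, size=idx.size)
            if d.allowed_range is not None:
                vals = np.clip(vals, *d.allowed_range)
            vals = np.round(vals, 3)
        else:
            draws = rng.random(idx.size) < gv.p_event
            vals = np.where(draws, d.levels[1], d.levels[0])
        keep = rng.random(idx.size) >= config.missingness_rate
        for j, v in zip(idx[keep], np.asarray(vals)[keep]):
            vrows.append((participants["participant_id"].iloc[j], d.name,
                          float(v) if d.kind == "continuous" else str(v)))
    values = pd.DataFrame(vrows, columns=[
        "participant_id", "variable_name", "value"])
    values = values.sort_values(["participant_id", "variable_name"],
                                kind="stable").reset_index(drop=True)
    values["value"] = values["value"].astype(object)

    dataset = TrialDataset(
        participants, entries, values,
        [gv.definition for gv in config.variable_panel],
        config.snapshot_date, allocation)
    return dataset, GroundTruth()


# --------------------------------------------------------------------------
# anomaly injection


def _centre_participants(dataset: TrialDataset, centre: str) -> pd.DataFrame:
    sub = dataset.participants[dataset.participants["centre_id"] == centre]
    if sub.empty:
        raise IntegrityError(f"unknown centre {centre!r}")
    return sub


def _require_variable(dataset: TrialDataset, name: str | None) -> str:
    if name is None or name not in dataset.variable_names:
        raise IntegrityError(f"unknown target variable {name!r}")
    return name


def _pooled_sd(dataset: TrialDataset, var: str) -> float:
    vals = pd.to_numeric(dataset.values.loc[
        dataset.values["variable_name"] == var, "value"], errors="coerce")
    sd = float(vals.std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ConfigError(f"{var}: pooled SD unavailable for shift anomaly")
    return sd


def inject_anomalies(dataset: TrialDataset, specs: Sequence[AnomalySpec],
                     seed: int) -> tuple[TrialDataset, GroundTruth]:
    """Plant the given deviations into a copy of the snapshot.

    Only records listed in the returned ground truth are changed.
    """
    rng = np.random.default_rng(seed)
    participants = dataset.participants.copy()
    entries = dataset.entries.copy()
    values = dataset.values.copy()
    truth = GroundTruth()

    for spec in specs:
        sub = _centre_participants(dataset, spec.target_centre)
        pids = sub["participant_id"].to_numpy()
        touched_pids: list[str] = []
        keys: list[tuple] = []

        if spec.kind in ("outlier", "misunderstanding"):
            var = _require_variable(dataset, spec.target_variable)
            vdef = dataset.variable(var)
            rows = values.index[(values["variable_name"] == var)
                                & values["participant_id"].isin(pids)]
            k = max(1, int(round(spec.affected_fraction * len(rows))))
            chosen = rng.choice(rows, size=min(k, len(rows)), replace=False)
            if vdef.kind == "continuous":
                if spec.kind == "outlier":      # unit-scale clerical error
                    values.loc[chosen, "value"] = [
                        float(v) * spec.magnitude
                        for v in values.loc[chosen, "value"]]
                else:                           # centre-wide systematic shift
                    shift = spec.magnitude * _pooled_sd(dataset, var)
                    values.loc[chosen, "value"] = [
                        float(v) + shift for v in values.loc[chosen, "value"]]
            else:                               # coded: systematic level swap
                lo, hi = vdef.levels
                values.loc[chosen, "value"] = [
                    hi if v == lo else lo for v in values.loc[chosen, "value"]]
            touched_pids = list(values.loc[chosen, "participant_id"])
            keys = [("values", p, var) for p in touched_pids]

        elif spec.kind == "fabrication":
            if spec.target_variable is not None:
                targets = [_require_variable(dataset, spec.target_variable)]
            else:
                targets = [v.name for v in dataset.dictionary
                           if v.kind == "continuous" and v.monitored]
            pid_set: set[str] = set()
            for var in targets:
                rows = values.index[(values["variable_name"] == var)
                                    & values["participant_id"].isin(pids)]
                if len(rows) == 0:
                    continue
                x = np.array([float(v) for v in values.loc[rows, "value"]])
                centre_mean = x.mean()
                shrunk = centre_mean + (x - centre_mean) * np.sqrt(
                    spec.magnitude)
                grid = max(_pooled_sd(dataset, var) / 2.0, 1e-9)
                fab = np.round(shrunk / grid) * grid
                values.loc[rows, "value"] = [float(v) for v in fab]
                pid_set.update(values.loc[rows, "participant_id"])
                keys += [("values", p, var)
                         for p in values.loc[rows, "participant_id"]]
            touched_pids = sorted(pid_set)

        elif spec.kind == "control_arm_monitoring":
            var = spec.target_variable or "unblinded_oximetry"
            var = _require_variable(dataset, var)
            vdef = dataset.variable(var)
            alloc = dataset.restricted_allocation()
            controls = [p for p in pids if alloc.get(p) == "control"]
            k = max(1, int(round(spec.affected_fraction * len(controls))))
            chosen_pids = list(rng.choice(controls, size=min(k, len(controls)),
                                          replace=False))
            rows = values.index[(values["variable_name"] == var)
                                & values["participant_id"].isin(chosen_pids)]
            values.loc[rows, "value"] = vdef.positive_level
            # participants with no emitted row get one (violation recorded)
            have = set(values.loc[rows, "participant_id"])
            new = [(p, var, vdef.positive_level)
                   for p in chosen_pids if p not in have]
            if new:
                values = pd.concat([values, pd.DataFrame(
                    new, columns=values.columns)], ignore_index=True)
            touched_pids = chosen_pids
            keys = [("values", p, var) for p in chosen_pids]

        elif spec.kind == "late_followup":
            mod = spec.target_variable or "36week_followup"
            rows = entries.index[(entries["module_name"] == mod)
                                 & entries["participant_id"].isin(pids)]
            if len(rows) == 0:
                raise IntegrityError(f"no {mod!r} entries at "
                                     f"{spec.target_centre}")
            k = max(1, int(round(spec.affected_fraction * len(rows))))
            chosen = rng.choice(rows, size=min(k, len(rows)), replace=False)
            for r in chosen:
                pid = entries.loc[r, "participant_id"]
                p = participants[participants["participant_id"] == pid].iloc[0]
                pma36 = (p["birth_datetime"].normalize() + pd.Timedelta(
                    days=int(252 - p["gestational_age_days"])))
                entries.loc[r, "completion_date"] = pma36 + pd.Timedelta(
                    days=int(spec.magnitude))
                entries.loc[r, "completed"] = True
                touched_pids.append(pid)
                keys.append(("entries", pid, mod))

        elif spec.kind == "missingness_burst":
            mod = spec.target_variable or "baseline"
            rows = entries.index[(entries["module_name"] == mod)
                                 & entries["participant_id"].isin(pids)]
            if len(rows) == 0:
                raise IntegrityError(f"no {mod!r} entries at "
                                     f"{spec.target_centre}")
            k = max(1, int(round(spec.affected_fraction * len(rows))))
            chosen = rng.choice(rows, size=min(k, len(rows)), replace=False)
            entries.loc[chosen, "completed"] = False
            entries.loc[chosen, "completion_date"] = pd.NaT
            touched_pids = list(entries.loc[chosen, "participant_id"])
            keys = [("entries", p, mod) for p in touched_pids]

        truth.planted.append(PlantedAnomaly(
            spec, tuple(touched_pids), tuple(keys)))

    out = TrialDataset(participants, entries, values, list(dataset.dictionary),
                       dataset.snapshot_date,
                       dataset._allocation.copy()
                       if dataset.has_allocation() else None)
    return out, truth
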