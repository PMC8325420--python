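"""Domain model for a multicentre-trial monitoring snapshot.

A snapshot is four flat tables — participants, data-entry module entries,
variable values (long format), and a variable dictionary — plus the date
the snapshot was taken.  The long value format tolerates per-centre
variable subsets and mirrors how electronic participant record forms
(ePRFs) store their instruments.

Group allocation is deliberately kept out of the participants table that
monitoring code sees: it is loaded into a restricted field that only the
control-arm quality indicator may read, so that completeness and anomaly
monitoring stay blinded to allocation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataParseError, IntegrityError, SchemaError

# --------------------------------------------------------------------------
# interchange schema (machine-readable; docs/schema.md is the prose version)

SCHEMA: dict = {
    "format": "trialmon-interchange",
    "version": 1,
    "encoding": "utf-8",
    "date_format": "YYYY-MM-DD",
    "datetime_format": "YYYY-MM-DD HH:MM",
    "boolean_values": ["true", "false"],
    "files": {
        "participants": {
            "columns": [
                "participant_id", "centre_id", "birth_datetime",
                "gestational_age_days", "randomisation_datetime",
                "allocation", "death_datetime", "consent_status",
            ],
            "restricted_columns": ["allocation"],
        },
        "entries": {
            "columns": [
                "participant_id", "module_name", "due_date",
                "completion_date", "completed",
            ],
        },
        "values": {
            "columns": ["participant_id", "variable_name", "value"],
        },
        "dictionary": {
            "columns": [
                "name", "kind", "unit", "range_min", "range_max",
                "levels", "monitored",
            ],
            "levels_separator": "|",
        },
    },
}

ALLOCATIONS = ("experimental", "control")
CONSENT_STATUSES = ("consented", "withdrawn", "declined")
VARIABLE_KINDS = ("continuous", "binary", "categorical")

#: catalogue of validation rules emitted by :func:`validate_dataset`
VALIDATION_RULES = {
    "range": "continuous value outside the variable's allowed range",
    "type": "continuous value is not numeric",
    "level": "coded value is not one of the variable's levels",
    "chronology": "dates out of order (birth/randomisation/death)",
    "ga_window": "gestational age outside the configured preterm window",
    "completed_without_date": "entry marked completed but has no completion date",
}


def dump_schema(path: str | Path) -> None:
    """Write the machine-readable interchange schema as JSON."""
    Path(path).write_text(json.dumps(SCHEMA, indent=2) + "\n")


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class VariableDef:
    """Definition of one monitored or auxiliary trial variable."""

    name: str
    kind: Literal["continuous", "binary", "categorical"]
    unit: str | None = None
    allowed_range: tuple[float, float] | None = None
    levels: tuple[str, ...] | None = None
    monitored: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ConfigError(f"unknown variable kind {self.kind!r}")
        if self.kind == "continuous":
            if self.allowed_range is not None:
                lo, hi = self.allowed_range
                if not lo < hi:
                    raise ConfigError(
                        f"{self.name}: allowed_range must have min < max")
        elif self.kind == "binary":
            if self.levels is None or len(self.levels) != 2:
                raise ConfigError(f"{self.name}: binary needs exactly 2 levels")
        elif self.levels is None or len(self.levels) < 2:
            raise ConfigError(f"{self.name}: categorical needs >= 2 levels")

    @property
    def positive_level(self) -> str:
        """Event level of a binary variable (by convention the second)."""
        if self.kind != "binary":
            raise ConfigError(f"{self.name} is not binary")
        return self.levels[1]


@dataclass
class MonitoringConfig:
    """Tunable monitoring parameters.

    Defaults follow standard central-monitoring practice: a 2-standard-
    deviation anomaly limit, 10,000 Monte-Carlo resamples, centres with
    fewer than 5 participants excluded from the anomaly analysis, variables
    with fewer than 5 entries suppressed, and a 36-week (252 days)
    postmenstrual-age follow-up window.
    """

    distance_threshold: float = 2.0
    n_resamples: int = 10_000
    min_participants_per_centre: int = 5
    min_entries_per_variable: int = 5
    followup_pma_days: int = 252
    rng_seed: int = 0
    covariance_shrinkage: float | str = "auto"
    followup_module: str = "36week_followup"
    exclude_withdrawn: bool = True
    ga_window_days: tuple[int, int] = (154, 195)
    variable_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0:
            raise ConfigError("distance_threshold must be > 0")
        for name in ("n_resamples", "min_participants_per_centre",
                     "min_entries_per_variable"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.followup_pma_days <= self.ga_window_days[1]:
            raise ConfigError(
                "followup_pma_days must exceed the maximum gestational age")
        if self.covariance_shrinkage != "auto":
            lam = float(self.covariance_shrinkage)
            if not 0.0 <= lam <= 1.0:
                raise ConfigError("covariance_shrinkage must be in [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MonitoringConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "ga_window_days" in raw:
            raw["ga_window_days"] = tuple(raw["ga_window_days"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["ga_window_days"] = list(d["ga_window_days"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass(frozen=True)
class Finding:
    """One validation finding; never an exception — monitoring detects,
    contacts, and corrects rather than silently cleaning."""

    participant_id: str
    field: str
    rule: str
    severity: Literal["error", "warning"]
    message: str


PARTICIPANT_COLUMNS = [
    "participant_id", "centre_id", "birth_datetime", "gestational_age_days",
    "randomisation_datetime", "death_datetime", "consent_status",
]
ENTRY_COLUMNS = [
    "participant_id", "module_name", "due_date", "completion_date", "completed",
]
VALUE_COLUMNS = ["participant_id", "variable_name", "value"]


@dataclass
class TrialDataset:
    """One monitoring snapshot of a multicentre trial.

    ``participants`` carries no allocation column; the restricted
    allocation series is reachable only through
    :meth:`restricted_allocation`.
    """

    participants: pd.DataFrame
    entries: pd.DataFrame
    values: pd.DataFrame
    dictionary: list[VariableDef]
    snapshot_date: date
    _allocation: pd.Series = dataclasses.field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.participants = self.participants.reset_index(drop=True)
        self.entries = self.entries.reset_index(drop=True)
        self.values = self.values.reset_index(drop=True)
        self._check_integrity()

    # -- accessors ---------------------------------------------------------

    def variable(self, name: str) -> VariableDef:
        for v in self.dictionary:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.dictionary]

    def restricted_allocation(self) -> pd.Series:
        """Group allocation keyed by participant_id.

        Restricted: only the control-arm oximetry quality indicator is
        entitled to call this; completeness and anomaly code must not.
        """
        if self._allocation is None:
            raise IntegrityError("allocation was withheld from this dataset")
        return self._allocation

    def has_allocation(self) -> bool:
        return self._allocation is not None

    def without_allocation(self) -> "TrialDataset":
        """Copy of the snapshot with the restricted field withheld."""
        return TrialDataset(
            self.participants.copy(), self.entries.copy(), self.values.copy(),
            list(self.dictionary), self.snapshot_date, None)

    def wide_values(self) -> pd.DataFrame:
        """Participant x variable table (missing entries stay NaN)."""
        if self.values.empty:
            return pd.DataFrame(index=pd.Index([], name="participant_id"))
        return self.values.pivot(index="participant_id",
                                 columns="variable_name", values="value")

    # -- integrity ---------------------------------------------------------

    def _check_integrity(self) -> None:
        ids = set(self.participants["participant_id"])
        if len(ids) != len(self.participants):
            dup = self.participants["participant_id"][
                self.participants["participant_id"].duplicated()].iloc[0]
            raise IntegrityError(f"duplicate participant_id {dup!r}")
        for tbl, label in ((self.entries, "entries"), (self.values, "values")):
            dangling = set(tbl["participant_id"]) - ids
            if dangling:
                raise IntegrityError(
                    f"{label} reference unknown participant(s): "
                    f"{', '.join(sorted(map(str, dangling)))}")
        known_vars = set(self.variable_names)
        dangling_vars = set(self.values["variable_name"]) - known_vars
        if dangling_vars:
            raise IntegrityError(
                "values reference undefined variable(s): "
                f"{', '.join(sorted(dangling_vars))}")
        if len(known_vars) != len(self.dictionary):
            raise IntegrityError("duplicate variable names in dictionary")
        dup_entry = self.entries.duplicated(["participant_id", "module_name"])
        if dup_entry.any():
            row = self.entries[dup_entry].iloc[0]
            raise IntegrityError(
                f"duplicate module entry ({row['participant_id']}, "
                f"{row['module_name']})")
        if self._allocation is not None:
            bad = set(self._allocation.dropna()) - set(ALLOCATIONS)
            if bad:
                raise IntegrityError(f"invalid allocation value(s): {bad}")

    def equals(self, other: "TrialDataset") -> bool:
        def norm(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
            return df.sort_values(keys).reset_index(drop=True)

        if self.snapshot_date != other.snapshot_date:
            return False
        if sorted(self.dictionary, key=lambda v: v.name) != sorted(
                other.dictionary, key=lambda v: v.name):
            return False
        pairs = [
            (self.participants, other.participants, ["participant_id"]),
            (self.entries, other.entries, ["participant_id", "module_name"]),
            (self.values, other.values, ["participant_id", "variable_name"]),
        ]
        for a, b, keys in pairs:
            if not norm(a, keys).equals(norm(b, keys)):
                return False
        a_alloc = (self._allocation.sort_index()
                   if self._allocation is not None else None)
        b_alloc = (other._allocation.sort_index()
                   if other._allocation is not None else None)
        if (a_alloc is None) != (b_alloc is None):
            return False
        return a_alloc is None or a_alloc.equals(b_alloc)


# --------------------------------------------------------------------------
# CSV interchange


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     fname: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing column(s) {', '.join(missing)}")


def _parse_dates(df: pd.DataFrame, col: str, fname: str) -> pd.Series:
    raw = df[col].astype("string")
    parsed = pd.to_datetime(raw, errors="coerce", format="mixed")
    bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataParseError(
            f"{fname} row {row + 2}: cannot parse {col}={raw.iloc[row]!r}")
    return parsed


def _parse_bool(df: pd.DataFrame, col: str, fname: str) -> pd.Series:
    raw = df[col].astype("string").str.strip().str.lower()
    ok = raw.isin(["true", "false"])
    if not ok.all():
        row = int(np.flatnonzero((~ok).to_numpy())[0])
        raise DataParseError(
            f"{fname} row {row + 2}: boolean {col}={df[col].iloc[row]!r}")
    return raw == "true"


def read_dictionary(path: str | Path) -> list[VariableDef]:
    df = pd.read_csv(path, dtype="string")
    _require_columns(df, SCHEMA["files"]["dictionary"]["columns"], "dictionary")
    defs: list[VariableDef] = []
    for _, row in df.iterrows():
        rng = None
        if pd.notna(row["range_min"]) and pd.notna(row["range_max"]):
            rng = (float(row["range_min"]), float(row["range_max"]))
        levels = None
        if pd.notna(row["levels"]) and row["levels"]:
            levels = tuple(row["levels"].split("|"))
        defs.append(VariableDef(
            name=row["name"], kind=row["kind"],
            unit=row["unit"] if pd.notna(row["unit"]) else None,
            allowed_range=rng, levels=levels,
            monitored=str(row["monitored"]).strip().lower() == "true"))
    return defs


def read_dataset(participants_path: str | Path, entries_path: str | Path,
                 values_path: str | Path, dictionary_path: str | Path,
                 snapshot_date: date | None = None) -> TrialDataset:
    """Load and validate one snapshot from the four interchange CSVs.

    ``snapshot_date`` falls back to a ``snapshot.json`` sidecar next to the
    participants file, then to the latest date present in the data.
    """
    dictionary = read_dictionary(dictionary_path)

    pdf = pd.read_csv(participants_path, dtype="string")
    _require_columns(pdf, SCHEMA["files"]["participants"]["columns"],
                     "participants")
    participants = pd.DataFrame({
        "participant_id": pdf["participant_id"].astype(object),
        "centre_id": pdf["centre_id"].astype(object),
        "birth_datetime": _parse_dates(pdf, "birth_datetime", "participants"),
        "gestational_age_days": pd.to_numeric(
            pdf["gestational_age_days"], errors="coerce").astype("Int64"),
        "randomisation_datetime": _parse_dates(
            pdf, "randomisation_datetime", "participants"),
        "death_datetime": _parse_dates(pdf, "death_datetime", "participants"),
        "consent_status": pdf["consent_status"].astype(str),
    })
    allocation = pd.Series(pdf["allocation"].astype(str).to_numpy(object),
                           index=pdf["participant_id"].astype(str
                                                             ).to_numpy(object),
                           name="allocation")

    edf = pd.read_csv(entries_path, dtype="string")
    _require_columns(edf, SCHEMA["files"]["entries"]["columns"], "entries")
    entries = pd.DataFrame({
        "participant_id": edf["participant_id"].astype(object),
        "module_name": edf["module_name"].astype(object),
        "due_date": _parse_dates(edf, "due_date", "entries"),
        "completion_date": _parse_dates(edf, "completion_date", "entries"),
        "completed": _parse_bool(edf, "completed", "entries"
                                 ).to_numpy(dtype=bool),
    })

    vdf = pd.read_csv(values_path, dtype="string")
    _require_columns(vdf, SCHEMA["files"]["values"]["columns"], "values")
    values = pd.DataFrame({
        "participant_id": vdf["participant_id"].astype(object),
        "variable_name": vdf["variable_name"].astype(object),
        "value": vdf["value"],
    })
    # continuous values become floats; coded values stay strings
    kinds = {v.name: v.kind for v in dictionary}
    cont = values["variable_name"].map(kinds) == "continuous"
    out = pd.Series(np.nan, index=values.index, dtype=object)
    out[cont] = pd.to_numeric(values.loc[cont, "value"],
                              errors="coerce").astype(object)
    keep = ~cont & values["value"].notna()
    out[keep] = values.loc[keep, "value"]
    values = values.assign(value=out)

    if snapshot_date is None:
        sidecar = Path(participants_path).parent / "snapshot.json"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            snapshot_date = date.fromisoformat(meta["snapshot_date"])
        else:
            candidates = pd.concat([
                entries["due_date"], entries["completion_date"],
                participants["birth_datetime"]]).dropna()
            snapshot_date = (candidates.max().date() if len(candidates)
                             else date.today())

    return TrialDataset(participants, entries, values, dictionary,
                        snapshot_date, allocation)


def _fmt_dt(s: pd.Series) -> pd.Series:
    return s.dt.strftime("%Y-%m-%d %H:%M")


def _fmt_date(s: pd.Series) -> pd.Series:
    return s.dt.strftime("%Y-%m-%d")


def write_dataset(dataset: TrialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four interchange CSVs (+ snapshot.json sidecar).

    Round-trip guarantee: ``read_dataset`` over the emitted files
    reproduces an equal dataset.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = dataset.participants
    alloc = (dataset._allocation if dataset.has_allocation()
             else pd.Series(dtype=object))
    pdf = pd.DataFrame({
        "participant_id": p["participant_id"],
        "centre_id": p["centre_id"],
        "birth_datetime": _fmt_dt(p["birth_datetime"]),
        "gestational_age_days": p["gestational_age_days"],
        "randomisation_datetime": _fmt_dt(p["randomisation_datetime"]),
        "allocation": p["participant_id"].map(alloc),
        "death_datetime": _fmt_dt(p["death_datetime"]),
        "consent_status": p["consent_status"],
    })
    e = dataset.entries
    edf = pd.DataFrame({
        "participant_id": e["participant_id"],
        "module_name": e["module_name"],
        "due_date": _fmt_date(e["due_date"]),
        "completion_date": _fmt_date(e["completion_date"]),
        "completed": e["completed"].map({True: "true", False: "false"}),
    })
    vdf = dataset.values.copy()
    ddf = pd.DataFrame([{
        "name": v.name, "kind": v.kind, "unit": v.unit,
        "range_min": v.allowed_range[0] if v.allowed_range else None,
        "range_max": v.allowed_range[1] if v.allowed_range else None,
        "levels": "|".join(v.levels) if v.levels else None,
        "monitored": "true" if v.monitored else "false",
    } for v in dataset.dictionary],
        columns=SCHEMA["files"]["dictionary"]["columns"])

    paths = {
        "participants": out / "participants.csv",
        "entries": out / "entries.csv",
        "values": out / "values.csv",
        "dictionary": out / "dictionary.csv",
    }
    pdf.to_csv(paths["participants"], index=False)
    edf.to_csv(paths["entries"], index=False)
    vdf.to_csv(paths["values"], index=False)
    ddf.to_csv(paths["dictionary"], index=False)
    (out / "snapshot.json").write_text(json.dumps(
        {"snapshot_date": dataset.snapshot_date.isoformat()}) + "\n")
    return paths


def read_dataset_dir(path: str | Path) -> TrialDataset:
    d = Path(path)
    return read_dataset(d / "participants.csv", d / "entries.csv",
                        d / "values.csv", d / "dictionary.csv")


# --------------------------------------------------------------------------
# validation


def validate_dataset(dataset: TrialDataset,
                     config: MonitoringConfig | None = None) -> list[Finding]:
    """Rule-based plausibility checks; returns findings, never raises.

    Every finding's ``rule`` is a key of :data:`VALIDATION_RULES`.
    Idempotent and side-effect free.
    """
    config = config or MonitoringConfig()
    findings: list[Finding] = []
    p = dataset.participants

    late_birth = p["randomisation_datetime"] < p["birth_datetime"]
    for pid in p.loc[late_birth.fillna(False), "participant_id"]:
        findings.append(Finding(pid, "randomisation_datetime", "chronology",
                                "error", "randomisation before birth"))
    early_death = p["death_datetime"] < p["birth_datetime"]
    for pid in p.loc[early_death.fillna(False), "participant_id"]:
        findings.append(Finding(pid, "death_datetime", "chronology",
                                "error", "death before birth"))
    lo, hi = config.ga_window_days
    ga_bad = (p["gestational_age_days"] < lo) | (p["gestational_age_days"] > hi)
    for pid in p.loc[ga_bad.fillna(False), "participant_id"]:
        findings.append(Finding(pid, "gestational_age_days", "ga_window",
                                "warning",
                                f"gestational age outside [{lo}, {hi}] days"))

    e = dataset.entries
    no_date = e["completed"] & e["completion_date"].isna()
    for _, row in e[no_date].iterrows():
        findings.append(Finding(row["participant_id"], row["module_name"],
                                "completed_without_date", "error",
                                "completed entry lacks a completion date"))

    defs = {v.name: v for v in dataset.dictionary}
    for _, row in dataset.values.dropna(subset=["value"]).iterrows():
        vdef = defs[row["variable_name"]]
        val = row["value"]
        if vdef.kind == "continuous":
            try:
                x = float(val)
            except (TypeError, ValueError):
                findings.append(Finding(row["participant_id"], vdef.name,
                                        "type", "error",
                                        f"non-numeric value {val!r}"))
                continue
            if vdef.allowed_range is not None:
                lo, hi = vdef.allowed_range
                if not lo <= x <= hi:
                    findings.append(Finding(
                        row["participant_id"], vdef.name, "range", "warning",
                        f"value {x:g} outside allowed range [{lo:g}, {hi:g}]"))
        elif vdef.levels is not None and str(val) not in vdef.levels:
            findings.append(Finding(row["participant_id"], vdef.name,
                                    "level", "error",
                                    f"value {val!r} not in levels"))
    return findings
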