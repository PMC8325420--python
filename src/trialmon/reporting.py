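"""Blinded report rendering and the monitoring decision log.

The central data monitoring group works blinded to centre identity: a
randomly generated acronym stands in for each centre in every rendered
document.  Four artifacts are produced per snapshot — full and short
completeness reports, full and short quality-and-deficiencies reports —
as deterministic markdown over CSV-backed tables.  The full quality
report shows the per-variable centre-stratified summaries first and the
Mahalanobis section in a separate trailing section, supporting the
two-pass review (first without, then with the distance results).

Flags, contacts and corrections live in an append-only JSON-lines log;
summary counts (how many flagged, contacted, corrected) are always
recomputed by folding over the log, never cached.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anomaly import DetectionResult
from .errors import AppendOnlyError, BlindingError, CapacityError, ConfigError
from .quality import INDICATOR_DESCRIPTIONS, QualitySummary
from .trial_model import MonitoringConfig, TrialDataset

ACRONYM_LENGTH = 4
DECISIONS = ("no_action", "contact_investigator", "amend_eprf", "remind_all")
RESOLUTIONS = ("open", "corrected", "confirmed_correct", "practice_changed")


# --------------------------------------------------------------------------
# blinding


@dataclass(frozen=True)
class BlindingMap:
    mapping: dict[str, str]
    seed: int

    def blind(self, centre_id: str) -> str:
        if centre_id == "ALL":
            return "ALL"
        try:
            return self.mapping[centre_id]
        except KeyError:
            raise BlindingError(
                f"centre {centre_id!r} has no acronym; refusing to emit a "
                "raw centre id") from None


def _acronym(index: int) -> str:
    letters = []
    for _ in range(ACRONYM_LENGTH):
        index, r = divmod(index, 26)
        letters.append(string.ascii_uppercase[r])
    return "".join(letters)


def _leaks(acronym: str, centre_id: str) -> bool:
    """True when the acronym shares a 3+-letter substring with the id."""
    cid = "".join(ch for ch in centre_id.upper() if ch.isalpha())
    a = acronym.upper()
    for n in range(3, ACRONYM_LENGTH + 1):
        for i in range(len(a) - n + 1):
            if a[i:i + n] in cid:
                return True
    return False


def assign_blinded_acronyms(centre_ids: list[str], seed: int) -> BlindingMap:
    """Unique 4-letter acronyms, sampled without replacement; the same
    seed reproduces the same map."""
    if not centre_ids:
        raise ConfigError("centre_ids is empty")
    space = 26 ** ACRONYM_LENGTH
    if len(centre_ids) > space:
        raise CapacityError(
            f"{len(centre_ids)} centres exceed the {space}-acronym space")
    rng = np.random.default_rng(seed)
    # draw a generous pool so leak-filtered centres still find a code
    pool_size = min(space, max(4 * len(centre_ids), 64))
    pool = iter(rng.choice(space, size=pool_size, replace=False))
    mapping: dict[str, str] = {}
    for cid in centre_ids:
        for idx in pool:
            code = _acronym(int(idx))
            if not _leaks(code, cid):
                mapping[cid] = code
                break
        else:
            raise CapacityError("acronym pool exhausted")
    return BlindingMap(mapping, seed)


# --------------------------------------------------------------------------
# monitoring decision log


@dataclass(frozen=True)
class FlagLogEntry:
    meeting_id: str
    flag_id: str
    blinded_centre: str
    item: str                       # variable / indicator / module reference
    observation: str
    decision: str
    resolution: str = "open"
    closure_note: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.decision not in DECISIONS:
            raise ConfigError(f"unknown decision {self.decision!r}")
        if self.resolution not in RESOLUTIONS:
            raise ConfigError(f"unknown resolution {self.resolution!r}")
        if (self.resolution != "open" and self.decision == "no_action"
                and not self.closure_note):
            raise ConfigError(
                "a closed entry needs a decision or a closure note")


class MonitoringLog:
    """Append-only sequence of flag entries.

    Corrections are recorded by appending a new entry for the same
    flag_id; existing entries are never rewritten.
    """

    def __init__(self, entries: list[FlagLogEntry] | None = None):
        self._entries: list[FlagLogEntry] = list(entries or [])

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def __getitem__(self, i: int) -> FlagLogEntry:
        return self._entries[i]

    def __setitem__(self, i, value) -> None:
        raise AppendOnlyError("log entries cannot be rewritten; append a "
                              "new entry for the same flag_id instead")

    def __delitem__(self, i) -> None:
        raise AppendOnlyError("log entries cannot be deleted")

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self._entries:
                fh.write(json.dumps(dataclasses.asdict(e)) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "MonitoringLog":
        entries = [FlagLogEntry(**json.loads(line))
                   for line in Path(path).read_text().splitlines() if line]
        return cls(entries)


def append_log_entry(log: MonitoringLog, entry: FlagLogEntry) -> MonitoringLog:
    """Append one entry; prior entries stay untouched."""
    log._entries.append(entry)
    return log


def summarise_log(log: MonitoringLog) -> dict:
    """Fold over the log: flagged / contacted / corrected counts and the
    rounded percentage shares reported in newsletters.

    Per flag_id the *latest* entry carries the current resolution, so a
    correction appended later supersedes the open state without
    rewriting history.
    """
    latest: dict[str, FlagLogEntry] = {}
    for e in log:
        latest[e.flag_id] = e
    entries = list(latest.values())
    flagged = len(entries)
    contacted = [e for e in entries if e.decision == "contact_investigator"]
    corrected = [e for e in contacted if e.resolution == "corrected"]
    res_counts = {r: sum(e.resolution == r for e in contacted)
                  for r in RESOLUTIONS}
    return {
        "flagged": flagged,
        "contacted": len(contacted),
        "corrected": len(corrected),
        "contacted_pct": (round(100 * len(contacted) / flagged)
                          if flagged else 0),
        "corrected_pct": (round(100 * len(corrected) / len(contacted))
                          if contacted else 0),
        "resolutions_of_contacted": res_counts,
    }


# --------------------------------------------------------------------------
# rendering


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    if isinstance(x, float):
        return f"{x:.3f}".rstrip("0").rstrip(".") if x % 1 else f"{x:.0f}"
    return str(x)


def _md_table(df: pd.DataFrame) -> str:
    if df.empty:
        return "_no data_\n"
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(_fmt(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def summarise_variables(dataset: TrialDataset,
                        config: MonitoringConfig | None = None
                        ) -> pd.DataFrame:
    """Per monitored variable x centre: n and summary statistic, with
    the randomisation groups combined.

    Centres below the participant floor are left out, and a centre's
    cell for a variable with fewer than ``min_entries_per_variable``
    entries is suppressed (NaN) — deficiencies cannot be judged on a
    handful of entries.
    """
    config = config or MonitoringConfig()
    wide = dataset.wide_values()
    centre_of = dataset.participants.set_index("participant_id")["centre_id"]
    sizes = centre_of.value_counts()
    centres = [c for c in sorted(sizes.index)
               if sizes[c] >= config.min_participants_per_centre]
    rows = []
    for v in dataset.dictionary:
        if not v.monitored or v.name not in wide.columns:
            continue
        col = wide[v.name]
        for c in centres:
            vals = col.loc[col.index.intersection(
                centre_of[centre_of == c].index)].dropna()
            n = len(vals)
            if n < config.min_entries_per_variable:
                rows.append((v.name, c, n, np.nan, np.nan))
            elif v.kind == "continuous":
                x = pd.to_numeric(vals, errors="coerce")
                rows.append((v.name, c, n, float(x.mean()), float(x.std())))
            else:
                p = float((vals == v.levels[-1]).mean()) if v.levels else np.nan
                rows.append((v.name, c, n, p, np.nan))
    return pd.DataFrame(rows, columns=["variable", "centre_id", "n",
                                       "statistic", "sd"])


@dataclass
class ReportBundle:
    full_completeness: str
    short_completeness: str
    full_quality: str
    short_quality: str
    tables: dict[str, pd.DataFrame]
    changelog: list[tuple[str, str, str]]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        docs = {
            "full_completeness.md": self.full_completeness,
            "short_completeness.md": self.short_completeness,
            "full_quality.md": self.full_quality,
            "short_quality.md": self.short_quality,
        }
        for name, text in docs.items():
            (out / name).write_text(text)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)


def _blind_participants(cells: pd.DataFrame,
                        blinding: BlindingMap) -> pd.DataFrame:
    """Replace centre ids with acronyms and participant ids with
    within-centre ordinals, so no raw identifier can leak."""
    out = cells.copy()
    out["centre"] = out["centre_id"].map(blinding.blind)
    ordinal = {}
    codes = []
    for _, row in out.iterrows():
        key = (row["centre_id"], row["participant_id"])
        if key not in ordinal:
            ordinal[key] = sum(k[0] == row["centre_id"] for k in ordinal) + 1
        codes.append(f"{row['centre']}-{ordinal[key]:03d}")
    out["participant"] = codes
    return out.drop(columns=["centre_id", "participant_id"])


def _header(title: str, meeting_meta: dict,
            changelog: list[tuple[str, str, str]]) -> str:
    lines = [f"# {title}", ""]
    for k in sorted(meeting_meta):
        lines.append(f"- {k}: {meeting_meta[k]}")
    lines += ["", "## Changelog", ""]
    for version, when, note in changelog:
        lines.append(f"- {version} ({when}): {note}")
    lines.append("")
    return "\n".join(lines)


def render_reports(cells: pd.DataFrame, completeness_table: pd.DataFrame,
                   quality: QualitySummary,
                   detection: DetectionResult | None,
                   blinding: BlindingMap, meeting_meta: dict,
                   variable_summary: pd.DataFrame | None = None,
                   config: MonitoringConfig | None = None,
                   log: MonitoringLog | None = None) -> ReportBundle:
    """Render the four report documents, all fully blinded.

    Byte-for-byte reproducible from the same inputs.  Raises
    BlindingError rather than ever emitting a raw centre id.
    """
    config = config or MonitoringConfig()
    changelog = meeting_meta.get(
        "changelog", [("1", meeting_meta.get("date", ""), "initial report")])
    meta = {k: v for k, v in meeting_meta.items() if k != "changelog"}

    # ---- completeness ----------------------------------------------------
    comp = completeness_table.copy()
    comp.insert(0, "centre", comp["centre_id"].map(blinding.blind))
    comp = comp.drop(columns=["centre_id"])

    full_cells = _blind_participants(cells, blinding)[
        ["centre", "participant", "module_name", "due_date",
         "completion_date", "status"]]
    full_cells = full_cells.assign(
        due_date=full_cells["due_date"].dt.strftime("%Y-%m-%d"),
        completion_date=full_cells["completion_date"].dt.strftime("%Y-%m-%d"))
    fc = [_header("Full data completeness report", meta, changelog),
          "## Per-participant module status", "",
          _md_table(full_cells)]
    full_completeness = "\n".join(fc)

    sc = [_header("Short data completeness report", meta, changelog),
          "## Completion proportion per centre and module", "",
          _md_table(comp)]
    short_completeness = "\n".join(sc)

    # ---- quality ---------------------------------------------------------
    small = {c for c, n in _centre_sizes(cells).items()
             if n < config.min_participants_per_centre}
    ind = quality.indicators.copy()
    ind_rendered = ind[~ind["centre_id"].isin(small)].copy()
    if not ind_rendered.empty:
        ind_rendered.insert(1, "centre",
                            ind_rendered["centre_id"].map(blinding.blind))
        ind_rendered = ind_rendered.drop(columns=["centre_id"])
        ind_rendered["description"] = ind_rendered["indicator_id"].map(
            INDICATOR_DESCRIPTIONS)

    fq = [_header("Full data quality and deficiencies report", meta,
                  changelog)]
    fq += ["## Variable summaries by centre (groups combined)", ""]
    if variable_summary is not None and not variable_summary.empty:
        vs = variable_summary.copy()
        vs.insert(1, "centre", vs["centre_id"].map(blinding.blind))
        vs = vs.drop(columns=["centre_id"])
        fq.append(_md_table(vs))
    else:
        fq.append("_no data_\n")
    fq += ["## Quality-deficiency indicators", "",
           _md_table(ind_rendered) if not ind_rendered.empty else "_no data_\n"]
    fq += [f"## Follow-up window ({config.followup_pma_days} days PMA)", ""]
    fq.append(f"Assessments after the window: {len(quality.followup_flags)}\n")
    fq += ["---", "", "## Mahalanobis distance (second review pass)", ""]
    if detection is not None:
        dt = detection.table().copy()
        dt.insert(0, "centre", dt["centre_id"].map(blinding.blind))
        dt = dt.drop(columns=["centre_id"])
        fq.append(_md_table(dt))
        fq.append(f"Shrinkage used: {detection.model.shrinkage_used}\n")
    else:
        fq.append("_no data_\n")
    full_quality = "\n".join(fq)

    overall = ind[ind["centre_id"] == "ALL"].copy()
    if not overall.empty:
        overall["description"] = overall["indicator_id"].map(
            INDICATOR_DESCRIPTIONS)
        overall = overall[["indicator_id", "description", "numerator",
                           "denominator", "proportion"]]
    sq = [_header("Short data quality and deficiencies report", meta,
                  changelog),
          "## Data presentation (all centres, groups combined)", "",
          _md_table(overall) if not overall.empty else "_no data_\n",
          "## Decisions of the monitoring group", ""]
    if log is not None and len(log):
        s = summarise_log(log)
        sq.append(f"- entries flagged: {s['flagged']}")
        sq.append(f"- investigators contacted: {s['contacted']} "
                  f"({s['contacted_pct']}%)")
        sq.append(f"- entries corrected: {s['corrected']} "
                  f"({s['corrected_pct']}%)")
        sq.append("")
    else:
        sq.append("_no decisions recorded_\n")
    short_quality = "\n".join(sq)

    tables = {
        "completeness_per_centre": comp,
        "indicators": (ind_rendered if not ind_rendered.empty
                       else pd.DataFrame()),
    }
    if detection is not None:
        dt = detection.table().copy()
        dt["centre_id"] = dt["centre_id"].map(blinding.blind)
        tables["distances"] = dt
        tables["exclusions"] = detection.exclusions().assign(
            name=lambda d: [blinding.blind(n) if w == "centre" else n
                            for w, n in zip(d["what"], d["name"])])
    return ReportBundle(full_completeness, short_completeness, full_quality,
                        short_quality, tables, changelog)


def _centre_sizes(cells: pd.DataFrame) -> dict[str, int]:
    return (cells.groupby("centre_id")["participant_id"].nunique().to_dict()
            if not cells.empty else {})
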