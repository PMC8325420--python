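"""Validation experiments for the monitoring toolkit.

Self-contained studies that exercise the full pipeline on synthetic
trials with known ground truth: a worked completeness example, the
flag-log arithmetic, a brute-force oracle for the Mahalanobis distance,
null calibration of the observed distances against the chi-square
reference, a power study for planted centre-level shifts, the exclusion
and follow-up-window rules, a blinding sweep over rendered reports, and
an end-to-end determinism check.

Problem sizes are chosen so the whole battery runs in a few minutes on
one CPU: the calibration study pools 10 replicate trials of 30 centres
by 40 participants; the power study uses 100 replicates of 20 centres
by 20 participants with the default 10,000 resamples.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy import stats

from .anomaly import (build_centre_features, detect, fit_common_model,
                      mahalanobis_distance, observed_distances)
from .completeness import compute_completeness, summarise_completeness
from .quality import check_followup_window, summarise_quality
from .reporting import (FlagLogEntry, MonitoringLog, append_log_entry,
                        assign_blinded_acronyms, render_reports,
                        summarise_log, summarise_variables)
from .synthgen import (AnomalySpec, SynthConfig, continuous_panel,
                       generate_trial, inject_anomalies)
from .trial_model import MonitoringConfig, TrialDataset, VariableDef


def _seed(base: int, offset: int) -> int:
    return int((base * 100_003 + offset) % (2 ** 31 - 1))


# --------------------------------------------------------------------------
# worked examples


def worked_completeness_example() -> float:
    """A centre that completed the 36-week instrument for 17 of the 20
    participants due: the completion proportion is 17/20."""
    n, done = 20, 17
    participants = pd.DataFrame({
        "participant_id": [f"P{i:02d}" for i in range(n)],
        "centre_id": "C01",
        "birth_datetime": pd.Timestamp("2021-01-01 08:00"),
        "gestational_age_days": pd.array([180] * n, dtype="Int64"),
        "randomisation_datetime": pd.Timestamp("2021-01-01 14:00"),
        "death_datetime": pd.NaT,
        "consent_status": "consented",
    })
    entries = pd.DataFrame({
        "participant_id": participants["participant_id"],
        "module_name": "36week_followup",
        "due_date": pd.Timestamp("2021-03-12"),
        "completion_date": [pd.Timestamp("2021-03-12")] * done
        + [pd.NaT] * (n - done),
        "completed": [True] * done + [False] * (n - done),
    })
    ds = TrialDataset(participants, entries,
                      pd.DataFrame(columns=["participant_id",
                                            "variable_name", "value"]),
                      [], dt.date(2021, 6, 1))
    table = summarise_completeness(
        compute_completeness(ds, dt.date(2021, 6, 1)))
    row = table[(table["centre_id"] == "C01")
                & (table["module_name"] == "36week_followup")]
    return float(row["proportion"].iloc[0])


def flag_workflow_shares(flagged: int = 156, contacted: int = 146,
                         corrected: int = 53) -> dict:
    """Fold the decision log of a monitoring period: how many entries
    were flagged, how many investigators contacted, how many entries
    corrected — and the rounded percentage shares."""
    log = MonitoringLog()
    for i in range(flagged):
        is_contacted = i < contacted
        append_log_entry(log, FlagLogEntry(
            meeting_id="m1-3", flag_id=f"F{i:03d}", blinded_centre="QXZP",
            item="entry", observation="flagged for review",
            decision=("contact_investigator" if is_contacted
                      else "no_action"),
            resolution=("corrected" if i < corrected
                        else "confirmed_correct" if is_contacted
                        else "open")))
    return summarise_log(log)


# --------------------------------------------------------------------------
# Mahalanobis oracle


def mahalanobis_oracle_diff(n_instances: int = 1000, seed: int = 0) -> float:
    """Largest absolute difference between the implementation and a
    direct dense linear solve over random instances of dimension <= 8."""
    from .anomaly import CommonModel

    rng = np.random.default_rng(_seed(seed, 1))
    worst = 0.0
    for _ in range(n_instances):
        p = int(rng.integers(1, 9))
        A = rng.normal(size=(p, p))
        sigma = A @ A.T + 0.5 * np.eye(p)
        mu, x = rng.normal(size=p), rng.normal(size=p)
        model = CommonModel(
            feature_names=[f"f{i}" for i in range(p)], location=mu,
            scale=np.ones(p), covariance=sigma, shrinkage_used=0.0,
            dropped_features=[], feature_index=np.arange(p),
            _chol=np.linalg.cholesky(sigma))
        ref = float(np.sqrt((x - mu) @ np.linalg.solve(sigma, x - mu)))
        worst = max(worst, abs(mahalanobis_distance(x, model) - ref))
    return worst


# --------------------------------------------------------------------------
# null calibration


def null_calibration(seed: int = 0, n_replicates: int = 10,
                     n_centres: int = 30, n_per_centre: int = 40,
                     n_features: int = 6) -> dict:
    """Observed squared distances of exchangeable clean centres against
    the chi-square(p) quantile at the two-sided 2-SD level.

    The chi-square reference is asymptotic in the number of centres:
    with the common mean and covariance estimated from the same n
    centres, d^2 * n/(n-1)^2 follows Beta(p/2, (n-p-1)/2) exactly, whose
    exceedance at this level is slightly below nominal (0.0185 vs 0.0455
    at n=30, p=6).  The replicate count keeps the binomial Monte-Carlo
    band wide enough that this documented small-sample bias does not
    masquerade as miscalibration.
    """
    nominal = 2 * stats.norm.sf(2.0)
    q = stats.chi2.ppf(1 - nominal, n_features)
    cfg = MonitoringConfig(covariance_shrinkage=0.0)
    exceed = total = 0
    for rep in range(n_replicates):
        ds, _ = generate_trial(SynthConfig(
            n_centres=n_centres, participants_per_centre=n_per_centre,
            variable_panel=continuous_panel(n_features),
            rng_seed=_seed(seed, 10 + rep)))
        feats = build_centre_features(ds, cfg)
        model = fit_common_model(feats, cfg)
        d = observed_distances(feats, model)
        exceed += int((d ** 2 > q).sum())
        total += len(d)
    rate = exceed / total
    band = 3 * np.sqrt(nominal * (1 - nominal) / total)
    return {"exceedance": rate, "nominal": nominal, "n_centres": total,
            "three_se_band": band,
            "within_band": bool(abs(rate - nominal) <= band)}


# --------------------------------------------------------------------------
# power / specificity


def power_study(seed: int = 0, n_replicates: int = 100,
                n_resamples: int = 10_000, shift_sd: float = 4.0) -> dict:
    """Planted-anomaly recovery and clean-data specificity.

    Each replicate is a 20-centre x 20-participant trial over a
    6-feature continuous panel.  In the shift arm one centre receives a
    centre-wide mean shift of ``shift_sd`` participant-level SDs on one
    monitored feature; it should be confirmed-flagged.  In the clean arm
    no centre should be confirmed.
    """
    cfg = MonitoringConfig(n_resamples=n_resamples)
    confirmed = 0
    clean_ok = 0
    for rep in range(n_replicates):
        ds, _ = generate_trial(SynthConfig(
            n_centres=20, participants_per_centre=20,
            variable_panel=continuous_panel(6),
            rng_seed=_seed(seed, 1000 + rep)))
        shifted, _ = inject_anomalies(ds, [AnomalySpec(
            "misunderstanding", "C01", "score_01", magnitude=shift_sd,
            affected_fraction=1.0)], seed=_seed(seed, 2000 + rep))
        res = detect(shifted, cfg, seed=_seed(seed, 3000 + rep))
        tiers = {f.centre_id: f.tier for f in res.flags}
        confirmed += tiers["C01"] == "confirmed"

        res_clean = detect(ds, cfg, seed=_seed(seed, 4000 + rep))
        clean_ok += all(f.tier != "confirmed" for f in res_clean.flags)
    return {"confirmed_rate": confirmed / n_replicates,
            "clean_replicates_without_confirmed": clean_ok / n_replicates,
            "n_replicates": n_replicates}


# --------------------------------------------------------------------------
# exclusion rules


def exclusion_rules_check(seed: int = 0) -> dict:
    """A 4-participant centre never enters the feature matrix; a feature
    with 4 entries at an included centre is dropped."""
    ds, _ = generate_trial(SynthConfig(
        n_centres=4, participants_per_centre=[4, 10, 10, 10],
        variable_panel=continuous_panel(3), missingness_rate=0.0,
        rng_seed=_seed(seed, 5)))
    feats = build_centre_features(ds)
    small_excluded = ("C01", "small_centre") in feats.excluded_centres \
        and "C01" not in feats.centre_ids

    v = ds.values
    drop = v.index[(v["variable_name"] == "score_02")
                   & v["participant_id"].str.startswith("C03")][:6]
    ds.values = v.drop(drop).reset_index(drop=True)   # 4 entries left at C03
    feats2 = build_centre_features(ds)
    sparse_dropped = ("score_02", "sparse_feature") in feats2.excluded_features
    return {"small_centre_excluded": small_excluded,
            "sparse_feature_dropped": sparse_dropped}


# --------------------------------------------------------------------------
# follow-up window recovery


def followup_recovery(seed: int = 0) -> dict:
    """Planted late follow-up dates are recovered exactly, and an
    assessment exactly on the 36+0-week PMA day is never flagged."""
    ds, _ = generate_trial(SynthConfig(
        n_centres=6, participants_per_centre=10,
        rng_seed=_seed(seed, 21)))
    planted, gt = inject_anomalies(ds, [
        AnomalySpec("late_followup", "C02", magnitude=5,
                    affected_fraction=0.5),
        AnomalySpec("late_followup", "C05", magnitude=1,
                    affected_fraction=0.3)], seed=_seed(seed, 22))
    flags, _ = check_followup_window(planted)
    truth = gt.participant_ids("late_followup")
    exact = {f.participant_id for f in flags} == truth

    # boundary: place one untouched participant exactly on the PMA day
    e = planted.entries
    p = planted.participants.set_index("participant_id")
    untouched = next(pid for pid in p.index
                     if pid not in truth and pid.startswith("C01"))
    pma36 = (p.loc[untouched, "birth_datetime"].normalize()
             + pd.Timedelta(days=int(252 - p.loc[untouched,
                                                 "gestational_age_days"])))
    mask = ((e["participant_id"] == untouched)
            & (e["module_name"] == "36week_followup"))
    planted.entries.loc[mask, "completion_date"] = pma36
    planted.entries.loc[mask, "completed"] = True
    flags2, _ = check_followup_window(planted)
    boundary_clean = untouched not in {f.participant_id for f in flags2}
    return {"n_planted": len(truth), "n_flagged": len(flags),
            "exact_recovery": exact, "boundary_not_flagged": boundary_clean}


# --------------------------------------------------------------------------
# blinding sweep and determinism


def _quality_map_for_scores() -> MonitoringConfig:
    roles = ("early_scan", "late_scan", "oximetry_start_hours",
             "oximetry_stopped_early", "severe_brain_injury",
             "phvd_or_atrophy", "unblinded_oximetry")
    return MonitoringConfig(variable_map={r: "score_01" for r in roles})


def _render_once(rng_seed: int, n_resamples: int = 200):
    ds, _ = generate_trial(SynthConfig(
        n_centres=5, participants_per_centre=8,
        variable_panel=continuous_panel(4), rng_seed=rng_seed))
    cfg = MonitoringConfig(n_resamples=n_resamples, rng_seed=rng_seed)
    cells = compute_completeness(ds, ds.snapshot_date, cfg)
    bundle = render_reports(
        cells, summarise_completeness(cells),
        summarise_quality(ds, _quality_map_for_scores()),
        detect(ds, cfg), assign_blinded_acronyms(
            sorted(ds.participants["centre_id"].unique()), rng_seed),
        {"meeting_id": "m1", "date": ds.snapshot_date.isoformat()},
        variable_summary=summarise_variables(ds, cfg), config=cfg)
    return bundle, sorted(ds.participants["centre_id"].unique())


def blinding_sweep(seed: int = 0, n_trials: int = 50) -> dict:
    """Render reports for many randomised synthetic trials and count
    raw centre identifiers leaking into the short (or any) document."""
    import re

    violations = 0
    for t in range(n_trials):
        bundle, centre_ids = _render_once(_seed(seed, 300 + t))
        pattern = re.compile("|".join(map(re.escape, centre_ids)))
        for doc in (bundle.short_completeness, bundle.short_quality,
                    bundle.full_completeness, bundle.full_quality):
            if pattern.search(doc):
                violations += 1
    return {"n_trials": n_trials, "violations": violations}


def determinism_check(seed: int = 0) -> bool:
    """Full pipeline run twice with the same seeds must be byte-equal:
    generated CSVs, report documents and every CSV-backed table."""
    outs = []
    for _ in range(2):
        ds, _ = generate_trial(SynthConfig(
            n_centres=6, participants_per_centre=8,
            rng_seed=_seed(seed, 77)))
        cfg = MonitoringConfig(n_resamples=500, rng_seed=_seed(seed, 78))
        cells = compute_completeness(ds, ds.snapshot_date, cfg)
        bundle = render_reports(
            cells, summarise_completeness(cells), summarise_quality(ds, cfg),
            detect(ds, cfg), assign_blinded_acronyms(
                sorted(ds.participants["centre_id"].unique()),
                _seed(seed, 79)),
            {"meeting_id": "m1", "date": ds.snapshot_date.isoformat()},
            variable_summary=summarise_variables(ds, cfg), config=cfg)
        outs.append((
            ds.values.to_csv(index=False), bundle.full_completeness,
            bundle.short_completeness, bundle.full_quality,
            bundle.short_quality,
            tuple(df.to_csv(index=False)
                  for df in bundle.tables.values())))
    return outs[0] == outs[1]
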