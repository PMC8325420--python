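import re

import pytest

from trialmon import (MonitoringConfig, SynthConfig, append_log_entry,
                      assign_blinded_acronyms, compute_completeness,
                      detect, generate_trial, render_reports,
                      summarise_completeness, summarise_log,
                      summarise_quality, summarise_variables)
from trialmon.errors import AppendOnlyError, BlindingError, CapacityError
from trialmon.reporting import FlagLogEntry, MonitoringLog
from trialmon.synthgen import continuous_panel

from conftest import build_dataset


def audit_trail_log() -> MonitoringLog:
    """A log with 156 flags: 146 contacted, of which 53 corrected."""
    log = MonitoringLog()
    for i in range(156):
        contacted = i < 146
        corrected = i < 53
        append_log_entry(log, FlagLogEntry(
            meeting_id="m1", flag_id=f"F{i:03d}", blinded_centre="QXZP",
            item="birth_weight_g", observation="implausible entry",
            decision="contact_investigator" if contacted else "no_action",
            resolution=("corrected" if corrected
                        else "confirmed_correct" if contacted else "open"),
            closure_note="" if contacted else "",
        ))
    return log


class TestAcronyms:
    def test_unique_and_reproducible(self):
        ids = [f"C{i:02d}" for i in range(1, 71)]
        m1 = assign_blinded_acronyms(ids, seed=7)
        m2 = assign_blinded_acronyms(ids, seed=7)
        assert m1 == m2
        codes = list(m1.mapping.values())
        assert len(set(codes)) == 70
        assert all(re.fullmatch(r"[A-Z]{4}", c) for c in codes)

    def test_different_seeds_differ(self):
        ids = [f"C{i:02d}" for i in range(1, 71)]
        a = assign_blinded_acronyms(ids, seed=7).mapping
        b = assign_blinded_acronyms(ids, seed=8).mapping
        assert any(a[c] != b[c] for c in ids)

    def test_single_centre(self):
        m = assign_blinded_acronyms(["HOSPITAL-X"], seed=1)
        assert len(m.mapping) == 1

    def test_acronym_never_echoes_the_centre_id(self):
        ids = ["SITEABCD", "ABCDEFGH"]
        m = assign_blinded_acronyms(ids, seed=3)
        for cid, code in m.mapping.items():
            for n in range(3, 5):
                for i in range(5 - n):
                    assert code[i:i + n] not in cid.upper()

    def test_capacity_error(self):
        too_many = [str(i) for i in range(26 ** 4 + 1)]
        with pytest.raises(CapacityError):
            assign_blinded_acronyms(too_many, seed=0)


class TestLog:
    def test_flag_workflow_shares_match_printed_percentages(self):
        s = summarise_log(audit_trail_log())
        assert (s["flagged"], s["contacted"], s["corrected"]) == (156, 146, 53)
        assert s["contacted_pct"] == 94
        assert s["corrected_pct"] == 36

    def test_empty_log_summarises_to_zero(self):
        s = summarise_log(MonitoringLog())
        assert (s["flagged"], s["contacted_pct"], s["corrected_pct"]) \
            == (0, 0, 0)

    def test_resolution_counts_partition_contacts(self):
        s = summarise_log(audit_trail_log())
        assert sum(s["resolutions_of_contacted"].values()) == s["contacted"]

    def test_log_is_append_only(self):
        log = audit_trail_log()
        n = len(log)
        with pytest.raises(AppendOnlyError):
            log[0] = log[1]
        with pytest.raises(AppendOnlyError):
            del log[0]
        assert len(log) == n

    def test_correction_supersedes_without_rewriting(self):
        log = MonitoringLog()
        append_log_entry(log, FlagLogEntry(
            "m1", "F1", "QXZP", "apgar_5min", "odd value",
            "contact_investigator", "open"))
        append_log_entry(log, FlagLogEntry(
            "m2", "F1", "QXZP", "apgar_5min", "investigator replied",
            "contact_investigator", "corrected"))
        s = summarise_log(log)
        assert (s["flagged"], s["corrected"]) == (1, 1)
        assert len(log) == 2

    def test_jsonl_round_trip(self, tmp_path):
        log = audit_trail_log()
        log.to_jsonl(tmp_path / "log.jsonl")
        back = MonitoringLog.from_jsonl(tmp_path / "log.jsonl")
        assert list(back) == list(log)


def render_bundle(seed=0, with_detection=True):
    ds, _ = generate_trial(SynthConfig(
        n_centres=5, participants_per_centre=8,
        variable_panel=continuous_panel(4), rng_seed=seed))
    cfg = MonitoringConfig(n_resamples=200, rng_seed=seed)
    cells = compute_completeness(ds, ds.snapshot_date, cfg)
    table = summarise_completeness(cells)
    qual = summarise_quality(ds, MonitoringConfig(
        variable_map={k: "score_01" for k in
                      ("early_scan", "late_scan", "oximetry_start_hours",
                       "oximetry_stopped_early", "severe_brain_injury",
                       "phvd_or_atrophy", "unblinded_oximetry")}))
    detection = detect(ds, cfg) if with_detection else None
    blinding = assign_blinded_acronyms(
        sorted(ds.participants["centre_id"].unique()), seed)
    bundle = render_reports(cells, table, qual, detection, blinding,
                            {"meeting_id": "m1", "date": "2021-05-24"},
                            variable_summary=summarise_variables(ds, cfg),
                            config=cfg)
    centre_ids = sorted(ds.participants["centre_id"].unique())
    return bundle, centre_ids


class TestRendering:
    def test_no_raw_centre_id_in_any_document(self):
        bundle, centre_ids = render_bundle()
        pattern = re.compile("|".join(map(re.escape, centre_ids)))
        for doc in (bundle.full_completeness, bundle.short_completeness,
                    bundle.full_quality, bundle.short_quality):
            assert not pattern.search(doc)
        for df in bundle.tables.values():
            assert not df.apply(
                lambda col: col.astype(str).str.contains(pattern)).any().any()

    def test_rendering_is_deterministic(self):
        a, _ = render_bundle(seed=2)
        b, _ = render_bundle(seed=2)
        assert a.full_quality == b.full_quality
        assert a.short_completeness == b.short_completeness

    def test_missing_centre_in_blinding_map_raises(self):
        ds, _ = generate_trial(SynthConfig(
            n_centres=4, participants_per_centre=6,
            variable_panel=continuous_panel(2), rng_seed=1))
        cfg = MonitoringConfig(n_resamples=100)
        cells = compute_completeness(ds, ds.snapshot_date, cfg)
        table = summarise_completeness(cells)
        qual = summarise_quality(ds, MonitoringConfig(
            variable_map={k: "score_01" for k in
                          ("early_scan", "late_scan", "oximetry_start_hours",
                           "oximetry_stopped_early", "severe_brain_injury",
                           "phvd_or_atrophy", "unblinded_oximetry")}))
        blinding = assign_blinded_acronyms(["C01", "C02", "C03"], 0)  # C04 missing
        with pytest.raises(BlindingError):
            render_reports(cells, table, qual, None, blinding,
                           {"meeting_id": "m1"}, config=cfg)

    def test_empty_inputs_render_no_data_sections(self):
        ds = build_dataset([{"pid": "P01", "centre": "C01"}])
        cfg = MonitoringConfig()
        cells = compute_completeness(ds, ds.snapshot_date, cfg)
        table = summarise_completeness(cells)
        qual = summarise_quality(ds)
        blinding = assign_blinded_acronyms(["C01"], 0)
        bundle = render_reports(cells, table, qual, None, blinding,
                                {"meeting_id": "m1"}, config=cfg)
        assert "_no data_" in bundle.full_quality
        assert "_no decisions recorded_" in bundle.short_quality

    def test_mahalanobis_section_trails_variable_summaries(self):
        bundle, _ = render_bundle(seed=3)
        doc = bundle.full_quality
        assert doc.index("Variable summaries") < doc.index("Mahalanobis")

    def test_log_summary_appears_in_short_quality_report(self):
        ds, _ = generate_trial(SynthConfig(
            n_centres=4, participants_per_centre=6,
            variable_panel=continuous_panel(2), rng_seed=4))
        cfg = MonitoringConfig(n_resamples=100)
        cells = compute_completeness(ds, ds.snapshot_date, cfg)
        qual = summarise_quality(ds, MonitoringConfig(
            variable_map={k: "score_01" for k in
                          ("early_scan", "late_scan", "oximetry_start_hours",
                           "oximetry_stopped_early", "severe_brain_injury",
                           "phvd_or_atrophy", "unblinded_oximetry")}))
        blinding = assign_blinded_acronyms(
            sorted(ds.participants["centre_id"].unique()), 0)
        bundle = render_reports(cells, summarise_completeness(cells), qual,
                                None, blinding, {"meeting_id": "m1"},
                                config=cfg, log=audit_trail_log())
        assert "146 (94%)" in bundle.short_quality
        assert "53 (36%)" in bundle.short_quality
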