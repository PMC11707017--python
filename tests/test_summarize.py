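import re

import numpy as np
import pandas as pd
import pytest
from helpers import START, episodes_oracle, make_series, random_episode_fixture

from cgmkit.metrics import MetricReport, metric_report
from cgmkit.summarize import (
    Finding,
    analyze_hyperglycemia,
    analyze_hypoglycemia,
    analyze_variability,
    assess_data_quality,
    detect_episodes,
    main_clinical_concern,
    render_narrative,
    summarize_case,
)


def series_with_block(base=120.0, block_value=60.0, block_start=36, block_len=4,
                      n=288, start=START):
    vals = np.full(n, base)
    vals[block_start:block_start + block_len] = block_value
    return make_series(vals, start=start)


class TestDetectEpisodes:
    def test_in_range_series_has_no_episodes(self):
        assert detect_episodes(make_series([100.0] * 50), 70, "below") == []

    def test_twenty_minutes_below_seventy_is_one_episode(self):
        s = series_with_block(block_value=60.0, block_len=4)
        eps = detect_episodes(s, 70, "below", level2_threshold=54)
        assert len(eps) == 1
        e = eps[0]
        assert e.duration_min == 20
        assert e.extremum == 60.0
        assert e.level == 1
        assert not e.prolonged

    def test_ten_minutes_is_below_minimum_duration(self):
        s = series_with_block(block_value=60.0, block_len=2)
        assert detect_episodes(s, 70, "below") == []

    def test_short_recovery_is_absorbed(self):
        vals = np.full(60, 120.0)
        vals[10:14] = 60.0   # 20 min out
        vals[14] = 100.0     # 5 min back in range (< 15 min recovery)
        vals[15:19] = 55.0   # out again
        eps = detect_episodes(make_series(vals), 70, "below", level2_threshold=54)
        assert len(eps) == 1
        assert eps[0].extremum == 55.0

    def test_full_recovery_splits_episodes(self):
        vals = np.full(60, 120.0)
        vals[10:14] = 60.0
        vals[14:18] = 120.0  # 20 min in range closes the first episode
        vals[18:22] = 60.0
        eps = detect_episodes(make_series(vals), 70, "below")
        assert len(eps) == 2

    def test_gap_terminates_open_episode(self):
        minutes = np.concatenate([np.arange(8) * 5, np.arange(8) * 5 + 100])
        vals = np.full(16, 60.0)
        times = START + pd.to_timedelta(minutes, unit="min")
        s = make_series(vals, times=times)
        eps = detect_episodes(s, 70, "below")
        assert len(eps) == 2  # no inference across the 60-min hole

    def test_nocturnal_and_level_flags(self):
        night = series_with_block(block_value=60.0, block_start=36, block_len=4)  # 03:00
        day = series_with_block(block_value=50.0, block_start=168, block_len=4)   # 14:00
        e_night = detect_episodes(night, 70, "below", level2_threshold=54)[0]
        e_day = detect_episodes(day, 70, "below", level2_threshold=54)[0]
        assert e_night.nocturnal and e_night.level == 1
        assert not e_day.nocturnal and e_day.level == 2

    def test_matches_run_length_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            s = random_episode_fixture(rng)
            for threshold, direction in ((70.0, "below"), (180.0, "above")):
                got = detect_episodes(s, threshold, direction)
                minutes = s.timestamps.asi8 / 60e9
                want = episodes_oracle(minutes, s.values, s.nominal_interval,
                                       threshold, direction)
                assert len(got) == len(want)
                for e, (w_start, w_last, w_ext) in zip(got, want):
                    assert e.start.value / 60e9 == pytest.approx(w_start)
                    assert e.duration_min == pytest.approx(
                        w_last - w_start + s.nominal_interval)
                    assert e.extremum == pytest.approx(w_ext)
                # disjoint and ordered
                for a, b in zip(got, got[1:]):
                    assert a.end <= b.start


class TestDataQuality:
    def test_complete_case_is_good(self):
        s = make_series(np.full(14 * 288, 120.0))
        f = assess_data_quality(s, expected_days=14)
        assert f.facts["verdict"] == "good"
        assert f.facts["pct_captured"] == 100.0

    def test_half_capture_is_insufficient(self):
        s = make_series(np.full(7 * 288, 120.0))
        f = assess_data_quality(s, expected_days=14)
        assert f.facts["verdict"] == "insufficient"
        assert "insufficient_data" in f.flags

    def test_empty_series(self):
        f = assess_data_quality(make_series([]), expected_days=14)
        assert f.facts["verdict"] == "insufficient"
        assert f.facts["days_active"] == 0


class TestHyperglycemia:
    def test_all_in_range_is_none_severity(self):
        f = analyze_hyperglycemia(make_series(np.full(288, 120.0)))
        assert f.facts["severity"] == "none"
        assert f.facts["n_prolonged_episodes"] == 0

    def test_three_hour_block_at_300_is_prolonged_on_that_day(self):
        vals = np.full(3 * 288, 140.0)
        day2 = 288 + 120  # 10:00 on day 2
        vals[day2:day2 + 36] = 300.0  # 3 h
        f = analyze_hyperglycemia(make_series(vals))
        assert f.facts["n_prolonged_episodes"] == 1
        assert f.facts["prolonged_episodes"][0]["start"].startswith("2024-03-02")
        assert f.facts["worst_days"][0][0] == "2024-03-02"

    def test_mild_case_never_called_notable(self):
        vals = np.concatenate([np.full(92, 140.0), np.full(8, 200.0)])
        f = analyze_hyperglycemia(make_series(vals))
        assert f.facts["severity"] == "mild"
        assert "notable" not in f.narrative.lower()


class TestHypoglycemia:
    def test_no_low_readings_no_episodes_no_near_miss(self):
        f = analyze_hypoglycemia(make_series(np.full(288, 120.0)))
        assert f.facts["n_episodes"] == 0
        assert f.facts["near_miss_count"] == 0

    def test_nocturnal_dip_is_level_one_and_surfaced(self):
        f = analyze_hypoglycemia(series_with_block(block_value=60.0,
                                                   block_start=36, block_len=4))
        assert f.facts["n_episodes"] == 1
        assert f.facts["n_nocturnal"] == 1
        assert f.facts["n_level2"] == 0
        assert "nocturnal" in f.narrative.lower()

    def test_afternoon_dip_to_fifty_is_level_two_not_nocturnal(self):
        f = analyze_hypoglycemia(series_with_block(block_value=50.0,
                                                   block_start=168, block_len=4))
        assert f.facts["n_level2"] == 1
        assert f.facts["n_nocturnal"] == 0
        assert "level 2" in f.narrative.lower()

    def test_overnight_near_miss_reported(self):
        s = series_with_block(block_value=75.0, block_start=24, block_len=6)  # 02:00
        f = analyze_hypoglycemia(s)
        assert f.facts["n_episodes"] == 0
        assert f.facts["near_miss_count"] == 6
        assert "approached" in f.narrative

    def test_absence_claim_censored_when_gaps_exist(self):
        minutes = np.concatenate([np.arange(100) * 5, np.arange(100) * 5 + 600])
        s = make_series(np.full(200, 120.0),
                        times=START + pd.to_timedelta(minutes, unit="min"))
        f = analyze_hypoglycemia(s)
        assert f.facts["n_episodes"] == 0
        assert "could not be assessed" in f.narrative

    def test_absence_claim_unqualified_without_gaps(self):
        f = analyze_hypoglycemia(make_series(np.full(288, 120.0)))
        assert "could not be assessed" not in f.narrative


class TestVariability:
    def test_constant_series(self):
        f = analyze_variability(make_series(np.full(288, 120.0)))
        assert f.facts["cv"] == 0.0
        assert f.facts["n_high_cv_days"] == 0

    def test_alternating_day_flagged(self):
        vals = np.full(3 * 288, 120.0)
        vals[288:576] = np.where(np.arange(288) % 2 == 0, 80.0, 240.0)
        f = analyze_variability(make_series(vals))
        assert f.facts["n_high_cv_days"] == 1
        assert f.facts["high_cv_days"][0][0] == "2024-03-02"
        assert f.facts["high_cv_days"][0][1] > 36

    def test_uniform_hyperglycemia_never_called_stable(self):
        f = analyze_variability(make_series(np.full(288, 250.0)))
        assert f.facts["cv"] == 0.0
        assert "stable" not in f.narrative.lower()

    def test_good_control_is_called_stable(self):
        f = analyze_variability(make_series(np.full(288, 120.0)))
        assert "stable" in f.narrative.lower()


def fake_findings(n_level2=0, n_nocturnal=0, n_episodes=0, cv=20.0):
    hypo = Finding(task="hypoglycemia", facts={
        "n_level2": n_level2, "n_nocturnal": n_nocturnal, "n_episodes": n_episodes})
    var = Finding(task="variability", facts={"cv": cv})
    return {"data_quality": Finding(task="data_quality", facts={}),
            "hyperglycemia": Finding(task="hyperglycemia", facts={}),
            "hypoglycemia": hypo, "variability": var}


def fake_report(gmi=6.5, tir=85.0, tbr=0.0, tar=10.0, cv=30.0):
    return MetricReport(
        days_active=14, pct_captured=100.0, mean_glucose=(gmi - 3.31) / 0.02392,
        gmi=gmi, cv=cv, pct_above_250=0.0, pct_above_180=tar, pct_70_180=tir,
        pct_below_70=tbr, pct_below_54=0.0)


class TestMainConcern:
    def test_meets_targets(self):
        f = main_clinical_concern(fake_report(gmi=6.5, tir=85.0, tbr=0.0, cv=30.0),
                                  fake_findings(cv=30.0))
        assert f.facts["concern"] == "meets_targets"
        assert "6.5" in f.narrative and "85.0" in f.narrative  # GMI and TIR restated

    def test_hypoglycemia_beats_hyperglycemia(self):
        f = main_clinical_concern(fake_report(gmi=6.2, tir=80.0, tbr=6.0),
                                  fake_findings(n_episodes=3))
        assert f.facts["concern"] == "hypoglycemia"

    def test_low_tir_is_hyperglycemia_burden(self):
        f = main_clinical_concern(fake_report(gmi=7.5, tir=40.0, tar=60.0),
                                  fake_findings())
        assert f.facts["concern"] == "hyperglycemia"

    def test_rule_order_level2_beats_nocturnal(self):
        f = main_clinical_concern(fake_report(tbr=5.0),
                                  fake_findings(n_level2=1, n_nocturnal=1, n_episodes=2))
        assert f.facts["concern"] == "hypoglycemia"

    def test_rule_order_nocturnal_beats_hyperglycemia(self):
        f = main_clinical_concern(fake_report(gmi=8.5, tir=50.0),
                                  fake_findings(n_nocturnal=1, n_episodes=1))
        assert f.facts["concern"] == "nocturnal_hypoglycemia"

    def test_rule_order_hyperglycemia_beats_variability(self):
        f = main_clinical_concern(fake_report(gmi=8.5, tir=50.0, cv=40.0),
                                  fake_findings(cv=40.0))
        assert f.facts["concern"] == "hyperglycemia"

    def test_variability_when_only_cv_high(self):
        f = main_clinical_concern(fake_report(gmi=6.8, tir=75.0, cv=40.0),
                                  fake_findings(cv=40.0))
        assert f.facts["concern"] == "variability"

    def test_missing_findings_rejected(self):
        with pytest.raises(ValueError, match="requires findings"):
            main_clinical_concern(fake_report(), {"hypoglycemia": None})

    def test_gmi_and_tir_always_restated(self):
        for kwargs in ({}, {"tbr": 6.0}, {"tir": 40.0}, {"cv": 45.0}):
            rep = fake_report(**kwargs)
            f = main_clinical_concern(rep, fake_findings(cv=rep.cv))
            assert f"{rep.gmi:.1f}" in f.narrative
            assert f"{rep.pct_70_180:.1f}" in f.narrative


class TestNarrative:
    def test_rendering_is_deterministic(self):
        f = analyze_hypoglycemia(series_with_block())
        assert render_narrative(f) == render_narrative(f) == f.narrative

    def test_sentence_count_within_two_to_six(self, suite_reports):
        for _, series, report in suite_reports[:4]:
            for task, finding in summarize_case(series, report).items():
                n = len(re.findall(r"[.!?](?:\s|$)", finding.narrative))
                assert 2 <= n <= 6, (task, finding.narrative)

    def test_overflow_truncated_to_six_keeping_highest_priority(self):
        sentences = tuple((p, f"Sentence number {p}.") for p in range(7))
        f = Finding(task="data_quality", facts={}, sentences=sentences)
        text = render_narrative(f)
        assert "number 6" not in text
        assert all(f"number {p}" in text for p in range(6))

    def test_every_numeral_traceable_to_facts(self, suite_reports):
        def flatten(x):
            if isinstance(x, dict):
                for v in x.values():
                    yield from flatten(v)
            elif isinstance(x, (list, tuple)):
                for v in x:
                    yield from flatten(v)
            elif isinstance(x, bool) or x is None:
                pass
            elif isinstance(x, (int, np.integer)):
                yield str(int(x))
            elif isinstance(x, float):
                yield f"{x:.1f}"
            else:
                yield str(x)

        for _, series, report in suite_reports[:4]:
            for task, finding in summarize_case(series, report).items():
                pool = " | ".join(flatten(finding.facts))
                for token in re.findall(r"\d+(?:\.\d+)?", finding.narrative):
                    assert token in pool, (task, token, finding.narrative)


class TestSuiteLevelBehavior:
    def test_high_gmi_cases_never_meet_targets(self, suite_reports):
        for config, series, report in suite_reports:
            if config.target_gmi >= 8.3:
                f = summarize_case(series, report)["main_concern"]
                assert f.facts["concern"] != "meets_targets"
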