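"""Dart detection and the resume-normal-swimming latency rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shoalwatch as sw
from shoalwatch.detect import SizeModel
from shoalwatch.latency import (
    DartEvent,
    events_from_darting_flags,
    read_events_csv,
)

SIZE = SizeModel(single_fish_area_cm2=8.0, body_length_cm=5.0)


def make_tracks(rows):
    """rows: (frame, track, speed_cmps, weight)"""
    rec = np.recarray(
        len(rows),
        dtype=[("frame", int), ("track", int), ("speed_cmps", float), ("weight", float)],
    )
    for k, r in enumerate(rows):
        rec[k] = r
    return rec


def brute_force_latency(events, duration, rule):
    """Independent window-scan oracle over the event list."""
    starts = np.arange(0.0, duration - rule.window_s + 1e-9, rule.window_step_s)
    if len(starts) == 0:
        starts = np.array([0.0])
    run = 0
    for s in starts:
        ids = {}
        for e in events:
            if s <= e.onset_s < s + rule.window_s:
                ids[e.object_id] = max(ids.get(e.object_id, 0), e.n_fish)
        if sum(ids.values()) < rule.max_darts_exclusive:
            run += 1
            if run >= rule.require_consecutive_windows:
                return s - (run - 1) * rule.window_step_s, False
        else:
            run = 0
    return duration, True


class TestDetectDarts:
    def test_all_speeds_below_threshold(self):
        tracks = make_tracks([(f, 0, 5.0, 1.0) for f in range(1, 20)])
        assert sw.detect_darts(tracks, SIZE, fps=10) == []

    def test_single_excursion_one_event_at_onset(self):
        # 5 frames at twice the threshold starting at frame 11
        rows = [(f, 0, 5.0, 1.0) for f in range(1, 11)]
        rows += [(f, 0, 2 * 3.0 * 5.0, 1.0) for f in range(11, 16)]
        rows += [(f, 0, 5.0, 1.0) for f in range(16, 20)]
        events = sw.detect_darts(make_tracks(rows), SIZE, fps=10)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(1.0)  # frame 10 at 10 fps
        assert events[0].peak_speed_cmps == pytest.approx(30.0)

    def test_short_excursion_ignored(self):
        rows = [(1, 0, 100.0, 1.0), (2, 0, 5.0, 1.0), (3, 0, 100.0, 1.0)]
        assert sw.detect_darts(make_tracks(rows), SIZE, fps=10, min_dart_frames=2) == []

    def test_two_tracks_two_events(self):
        rows = [(f, t, 100.0, 1.0) for t in (0, 1) for f in range(1, 4)]
        events = sw.detect_darts(make_tracks(rows), SIZE, fps=10)
        assert len(events) == 2
        assert {e.object_id for e in events} == {0, 1}

    def test_detected_windows_correlate_with_ground_truth(self, stimulus_recovery):
        # detected events per 10 s window track the true darting onsets
        r = stimulus_recovery
        win = np.arange(0, 60, 10)
        det_counts = [
            sum(1 for e in r["events"] if s <= e.onset_s < s + 10) for s in win
        ]
        true_counts = [
            sum(1 for e in r["gt_events"] if s <= e.onset_s < s + 10) for s in win
        ]
        rho = np.corrcoef(det_counts, true_counts)[0, 1]
        assert rho >= 0.8


class TestLatencyRule:
    def test_no_events_latency_zero(self):
        res = sw.latency_to_resume([], clip_duration_s=60.0)
        assert res.latency_s == 0.0 and not res.censored

    def test_staircase_counts_latency_40s(self):
        # consecutive 10 s windows with 5,4,3,2,1,0 distinct darting fish:
        # first window with < 2 is the fifth, so latency is 40 s
        events = []
        counts = [5, 4, 3, 2, 1, 0]
        fid = 0
        for w, c in enumerate(counts):
            for k in range(c):
                events.append(DartEvent(onset_s=10.0 * w + k * 0.5, object_id=fid))
                fid += 1
        rule = sw.LatencyRule(window_step_s=10.0)
        res = sw.latency_to_resume(events, clip_duration_s=60.0, rule=rule)
        assert res.latency_s == 40.0
        oracle_latency, oracle_cens = brute_force_latency(events, 60.0, rule)
        assert res.latency_s == oracle_latency and res.censored == oracle_cens

    def test_persistent_darting_censored(self):
        events = [
            DartEvent(onset_s=t, object_id=i)
            for t in np.arange(0, 60, 2.0)
            for i in (0, 1)
        ]
        res = sw.latency_to_resume(events, clip_duration_s=60.0)
        assert res.censored and res.latency_s == 60.0

    def test_multi_fish_object_counts_as_its_size(self):
        # one darting object of ~2 fish-equivalents blocks the <2 rule alone
        events = [DartEvent(onset_s=t, object_id=0, n_fish=2) for t in range(0, 60, 5)]
        res = sw.latency_to_resume(events, clip_duration_s=60.0)
        assert res.censored

    @settings(max_examples=100, deadline=None, derandomize=True, database=None)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.0, 59.9, allow_nan=False), st.integers(0, 6)
            ),
            max_size=40,
        ),
        step=st.sampled_from([1.0, 5.0, 10.0]),
    )
    def test_matches_brute_force_oracle(self, data, step):
        events = sorted(
            (DartEvent(onset_s=t, object_id=i) for t, i in data),
            key=lambda e: e.onset_s,
        )
        rule = sw.LatencyRule(window_step_s=step)
        res = sw.latency_to_resume(events, clip_duration_s=60.0, rule=rule)
        lat, cens = brute_force_latency(events, 60.0, rule)
        assert res.latency_s == pytest.approx(lat)
        assert res.censored == cens

    @settings(max_examples=60, deadline=None, derandomize=True, database=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(0.0, 59.9, allow_nan=False), st.integers(0, 6)),
            max_size=25,
        )
    )
    def test_rule_relaxation_monotone(self, data):
        # latency is non-increasing as the darting-count ceiling rises
        events = [DartEvent(onset_s=t, object_id=i) for t, i in data]
        lats = [
            sw.latency_to_resume(
                events, 60.0, rule=sw.LatencyRule(max_darts_exclusive=m)
            ).latency_s
            for m in (1, 2, 4, 8)
        ]
        assert all(b <= a for a, b in zip(lats, lats[1:]))

    @settings(max_examples=60, deadline=None, derandomize=True, database=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(0.0, 59.9, allow_nan=False), st.integers(0, 6)),
            min_size=1,
            max_size=25,
        ),
        drop=st.integers(1, 5),
    )
    def test_superset_of_events_never_shortens_latency(self, data, drop):
        events = [DartEvent(onset_s=t, object_id=i) for t, i in data]
        subset = events[: max(0, len(events) - drop)]
        full = sw.latency_to_resume(events, 60.0).latency_s
        sub = sw.latency_to_resume(subset, 60.0).latency_s
        assert full >= sub


class TestExport:
    def test_sqrt_transform(self):
        results = [
            sw.LatencyResult(0.0, False, 60.0, tank_id="T1", trial=1),
            sw.LatencyResult(25.0, False, 60.0, tank_id="T1", trial=2),
            sw.LatencyResult(60.0, True, 60.0, tank_id="T1", trial=3),
        ]
        df = sw.sqrt_transform_export(results)
        assert df["sqrt_latency"].tolist() == pytest.approx([0.0, 5.0, np.sqrt(60.0)])
        assert df["censored"].tolist() == [False, False, True]

    def test_external_events_csv_round_trip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "events.csv"
        pd.DataFrame(
            {"time_s": [1.0, 2.5, 40.0], "subject_id": [0, 1, 0]}
        ).to_csv(path, index=False)
        events = read_events_csv(path)
        assert [e.onset_s for e in events] == [1.0, 2.5, 40.0]
        res = sw.latency_to_resume(events, clip_duration_s=60.0)
        assert not res.censored

    def test_ground_truth_flag_events(self):
        flags = np.zeros((10, 2), dtype=bool)
        flags[3:6, 0] = True
        flags[8, 1] = True
        events = events_from_darting_flags(flags, fps=10.0)
        assert [(e.onset_s, e.object_id) for e in events] == [(0.3, 0), (0.8, 1)]
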