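import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tastecoda.extraction import (
    SessionData,
    align_trial_window,
    build_response_table,
    classify_response,
    compute_delta,
    filter_tracked,
    summarize_responses,
)


def _trial(trial_id=0, onset=60.0):
    return pd.Series({"trial_id": trial_id, "onset_s": onset, "stimulus": "NaCl"})


def _licks(times, trial_id=0):
    return pd.DataFrame({"trial_id": trial_id, "lick_time_s": list(times)})


class TestAlignTrialWindow:
    def test_lick_anchored_spans(self):
        b, r, anchor = align_trial_window(_trial(onset=98.0), _licks([100.0]), 10.0)
        assert b == (950, 1000)
        assert r == (1000, 1050)
        assert anchor == "lick"

    def test_zero_licks_anchor_at_onset(self):
        b, r, anchor = align_trial_window(_trial(onset=60.0), _licks([]), 10.0)
        assert b == (550, 600)
        assert r == (600, 650)
        assert anchor == "onset"

    def test_late_first_lick_moves_spans(self):
        # first lick 2 s after onset: spans follow the lick, not the onset
        b, r, anchor = align_trial_window(_trial(onset=60.0), _licks([62.0]), 10.0)
        assert r == (620, 670)
        assert b == (570, 620)
        assert anchor == "lick"

    def test_licks_outside_trial_window_ignored(self):
        # the lick at 10 s precedes the trial; the first in-window lick anchors
        b, r, anchor = align_trial_window(
            _trial(onset=60.0), _licks([10.0, 63.0]), 10.0)
        assert anchor == "lick"
        assert r[0] == 630

    def test_only_out_of_window_licks_fall_back_to_onset(self):
        b, r, anchor = align_trial_window(
            _trial(onset=60.0), _licks([10.0, 66.0]), 10.0)
        assert anchor == "onset"
        assert r[0] == 600

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="outside recording"):
            align_trial_window(_trial(onset=2.0), _licks([]), 10.0)
        with pytest.raises(ValueError, match="outside recording"):
            align_trial_window(_trial(onset=60.0), _licks([]), 10.0, n_frames=640)


class TestComputeDelta:
    def test_constant_trace(self):
        trace = np.ones(200)
        dp, dm, sd = compute_delta(trace, (50, 100), (100, 150))
        assert dp == 0.0
        assert dm == 0.0
        assert sd == pytest.approx(1e-6)  # floor for zero dynamic range

    def test_known_extrema(self):
        trace = np.ones(200)
        trace[120] = 4.0
        trace[130] = 0.5
        dp, dm, _ = compute_delta(trace, (50, 100), (100, 150))
        assert dp == pytest.approx(3.0)
        assert dm == pytest.approx(-0.5)

    def test_nan_raises(self):
        trace = np.ones(200)
        trace[110] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            compute_delta(trace, (50, 100), (100, 150))

    @settings(max_examples=30, deadline=None)
    @given(shift=st.floats(-100, 100), seed=st.integers(0, 1000))
    def test_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        trace = rng.normal(1.0, 0.3, 200)
        a = compute_delta(trace, (50, 100), (100, 150))
        b = compute_delta(trace + shift, (50, 100), (100, 150))
        assert a[0] == pytest.approx(b[0], abs=1e-9)
        assert a[1] == pytest.approx(b[1], abs=1e-9)
        assert a[2] == pytest.approx(b[2], abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(0.01, 50), seed=st.integers(0, 1000))
    def test_scale_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        trace = rng.normal(1.0, 0.3, 200)
        dp, dm, sd = compute_delta(trace, (50, 100), (100, 150))
        dp2, dm2, sd2 = compute_delta(trace * scale, (50, 100), (100, 150))
        assert dp2 == pytest.approx(dp * scale, rel=1e-9)
        assert dm2 == pytest.approx(dm * scale, rel=1e-9)
        assert sd2 == pytest.approx(sd * scale, rel=1e-9)
        assert classify_response(dp, dm, sd) == classify_response(dp2, dm2, sd2)


class TestClassifyResponse:
    def test_inclusive_excited_boundary(self):
        assert classify_response(3.0, 0.0, 1.0) == "excited"

    def test_subthreshold_is_none(self):
        assert classify_response(2.9, -1.0, 1.0) == "none"

    def test_suppressed(self):
        assert classify_response(0.5, -3.5, 1.0) == "suppressed"

    def test_excited_wins_dual(self):
        assert classify_response(3.5, -3.5, 1.0) == "excited"

    def test_nonpositive_sd_raises(self):
        with pytest.raises(ValueError):
            classify_response(1.0, 0.0, 0.0)


def _make_session(traces, ids, animal="A", day="pretest1", trials=None, licks=None):
    n_frames = traces.shape[1]
    if trials is None:
        trials = pd.DataFrame({"trial_id": [0], "stimulus": ["NaCl"],
                               "onset_s": [10.0], "block": [1], "forced": [False]})
    if licks is None:
        licks = pd.DataFrame({"trial_id": [], "lick_time_s": []})
    return SessionData(animal_id=animal, day=day, day_kind="pretest",
                       group="CON", traces=traces, frame_rate=10.0,
                       trials=trials, licks=licks,
                       global_cell_ids=np.asarray(ids))


class TestFilterTracked:
    def test_cell_missing_on_one_day_excluded(self):
        rng = np.random.default_rng(0)
        days = [_make_session(rng.normal(size=(3, 300)), [1, 2, 3], day="d1"),
                _make_session(rng.normal(size=(2, 300)), [1, 3], day="d2")]
        out, report = filter_tracked(days)
        for s in out:
            assert s.global_cell_ids.tolist() == [1, 3]
        assert report["n_tracked"].iloc[0] == 2

    def test_perfect_registry_keeps_all(self, small_cohort):
        imaging = [s for s in small_cohort.sessions if s.day_kind != "conditioning"]
        out, report = filter_tracked(imaging)
        assert (report["n_tracked"] == small_cohort.config.n_cells_per_animal).all()

    def test_random_dropout_matches_brute_force_intersection(self):
        rng = np.random.default_rng(42)
        all_ids = np.arange(30)
        sessions, kept_sets = [], []
        for d in range(4):
            keep = all_ids[rng.random(30) > 0.2]
            kept_sets.append(set(keep.tolist()))
            sessions.append(_make_session(
                rng.normal(size=(len(keep), 300)), keep, day=f"d{d}"))
        expected = sorted(set.intersection(*kept_sets))
        out, _ = filter_tracked(sessions)
        if expected:
            for s in out:
                assert s.global_cell_ids.tolist() == expected
        else:
            assert out == []

    def test_zero_tracked_animal_dropped(self):
        rng = np.random.default_rng(0)
        sessions = [_make_session(rng.normal(size=(2, 300)), [1, 2], day="d1"),
                    _make_session(rng.normal(size=(2, 300)), [3, 4], day="d2")]
        out, report = filter_tracked(sessions)
        assert out == []
        assert report["n_tracked"].iloc[0] == 0


class TestAveraging:
    def test_day_mean_matches_brute_force(self, small_table):
        trials = small_table.trials
        avg = small_table.averaged
        # brute-force oracle: plain Python loop over rows
        sums: dict = {}
        for row in trials.itertuples():
            key = (row.animal, row.day, row.cell, row.stimulus)
            s, n = sums.get(key, (0.0, 0))
            sums[key] = (s + row.delta_plus, n + 1)
        for row in avg.itertuples():
            key = (row.animal, row.day, row.cell, row.stimulus)
            s, n = sums[key]
            assert row.delta_plus == pytest.approx(s / n, rel=1e-12)
            assert row.n_trials == n

    def test_shift_invariance_of_full_extraction(self, small_cohort):
        session = [s for s in small_cohort.sessions
                   if s.day_kind != "conditioning"][0]
        shifted = SessionData(
            animal_id=session.animal_id, day=session.day,
            day_kind=session.day_kind, group=session.group,
            traces=session.traces + 7.5, frame_rate=session.frame_rate,
            trials=session.trials, licks=session.licks,
            global_cell_ids=session.global_cell_ids)
        a = build_response_table([session]).trials
        b = build_response_table([shifted]).trials
        pd.testing.assert_frame_equal(a, b)


class TestSdScope:
    def test_session_scope_pools_baseline_sd_per_cell(self, small_cohort):
        session = [s for s in small_cohort.sessions
                   if s.day_kind != "conditioning"][0]
        table = build_response_table([session], sd_scope="session")
        per_cell = table.trials.groupby("cell")["baseline_sd"].nunique()
        assert (per_cell == 1).all()
        per_trial = build_response_table([session]).trials
        assert per_trial.groupby("cell")["baseline_sd"].nunique().max() > 1

    def test_unknown_scope_raises(self, small_cohort):
        session = small_cohort.sessions[0]
        with pytest.raises(ValueError, match="sd_scope"):
            build_response_table([session], sd_scope="weekly")


class TestSummaries:
    def test_flat_cohort_fraction_zero_magnitudes_null(self):
        traces = np.ones((5, 400))
        trials = pd.DataFrame({
            "trial_id": [0, 1], "stimulus": ["NaCl", "sucrose"],
            "onset_s": [10.0, 25.0], "block": [1, 1], "forced": [False, False]})
        session = _make_session(traces, np.arange(5), trials=trials)
        table = build_response_table([session])
        summ = summarize_responses(table)
        pooled = summ[summ["stimulus"] == "all"].iloc[0]
        assert pooled["fraction_perturbed"] == 0.0
        assert np.isnan(pooled["mean_excited_magnitude"])
        assert np.isnan(pooled["mean_suppressed_magnitude"])

    def test_known_fraction(self):
        traces = np.ones((10, 400))
        # drive cells 0..2 during the response window of trial 0 (NaCl)
        traces[:3, 105:150] += 5.0
        trials = pd.DataFrame({
            "trial_id": [0], "stimulus": ["NaCl"], "onset_s": [10.0],
            "block": [1], "forced": [False]})
        session = _make_session(traces, np.arange(10), trials=trials)
        summ = summarize_responses(build_response_table([session]))
        nacl = summ[summ["stimulus"] == "NaCl"].iloc[0]
        assert nacl["fraction_perturbed"] == pytest.approx(0.3)
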