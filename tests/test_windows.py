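"""Time-in-bed detection: features, Viterbi smoothing, merging, selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sleepstagekit.core import EpochTensor, TimeInBedWindow
from sleepstagekit.windows import (
    FEATURE_NAMES,
    extract_features,
    fit_window_model,
    merge_windows,
    predict_time_in_bed,
    rf_stage_baseline,
    select_overnight_window,
    viterbi,
)

FIDX = {name: i for i, name in enumerate(FEATURE_NAMES)}


def _tensor_from_epochs(epochs):
    epochs = np.asarray(epochs, dtype=np.float32)
    n = epochs.shape[0]
    times = pd.date_range("2024-01-01", periods=n, freq="30s")
    return EpochTensor(epochs, times, np.ones(n, dtype=bool))


class TestExtractFeatures:
    def test_constant_vertical_epoch(self):
        """(0,0,1) g: zero ENMO, zero sds, arm angle 90 degrees."""
        epoch = np.zeros((1, 3, 900))
        epoch[0, 2] = 1.0
        X, _ = extract_features(_tensor_from_epochs(epoch))
        assert X[0, FIDX["enmo_mean_mg"]] == pytest.approx(0.0, abs=1e-9)
        for ax in "xyz":
            assert X[0, FIDX[f"sd_{ax}"]] == pytest.approx(0.0, abs=1e-9)
        assert X[0, FIDX["arm_angle_mean_deg"]] == pytest.approx(90.0)

    def test_sinusoid_sd_is_amplitude_over_sqrt2(self):
        """50 mg sinusoid at 1 Hz on x: per-axis sd = 50/sqrt(2) mg within 1%."""
        t = np.arange(900) / 30.0
        epoch = np.zeros((1, 3, 900))
        epoch[0, 0] = 0.050 * np.sin(2 * np.pi * 1.0 * t)
        epoch[0, 2] = 1.0
        X, _ = extract_features(_tensor_from_epochs(epoch))
        expected = 0.050 / np.sqrt(2)
        assert X[0, FIDX["sd_x"]] == pytest.approx(expected, rel=0.01)

    def test_identical_epochs_zero_angle_change(self):
        epoch = np.zeros((2, 3, 900))
        epoch[:, 2] = 1.0
        epoch[:, 0] = 0.3
        X, _ = extract_features(_tensor_from_epochs(epoch))
        assert X[1, FIDX["arm_angle_change_deg"]] == pytest.approx(0.0, abs=1e-9)

    def test_all_nonwear_gives_empty_matrix(self):
        epochs = np.zeros((3, 3, 900), dtype=np.float32)
        tensor = EpochTensor(epochs, pd.date_range("2024-01-01", periods=3, freq="30s"),
                             np.zeros(3, dtype=bool))
        X, times = extract_features(tensor)
        assert X.shape == (0, len(FEATURE_NAMES)) and len(times) == 0


def _bruteforce_best_path(log_start, log_trans, log_lik):
    T, S = log_lik.shape
    best, best_score = None, -np.inf
    for path in itertools.product(range(S), repeat=T):
        score = log_start[path[0]] + log_lik[0, path[0]]
        for t in range(1, T):
            score += log_trans[path[t - 1], path[t]] + log_lik[t, path[t]]
        if score > best_score + 1e-12:
            best, best_score = path, score
    return np.array(best)


class TestViterbi:
    @given(st.integers(0, 2**31 - 1), st.integers(1, 12))
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_enumeration(self, seed, T):
        """Decoder equals brute-force search over all 2^T binary paths."""
        rng = np.random.default_rng(seed)
        log_start = np.log(rng.dirichlet([1, 1]))
        log_trans = np.log(rng.dirichlet([1, 1], size=2))
        log_lik = rng.normal(0, 2, size=(T, 2))
        got = viterbi(log_start, log_trans, log_lik)
        expected = _bruteforce_best_path(log_start, log_trans, log_lik)
        s_got = log_start[got[0]] + log_lik[0, got[0]] + sum(
            log_trans[got[t - 1], got[t]] + log_lik[t, got[t]] for t in range(1, T)
        )
        s_exp = log_start[expected[0]] + log_lik[0, expected[0]] + sum(
            log_trans[expected[t - 1], expected[t]] + log_lik[t, expected[t]]
            for t in range(1, T)
        )
        assert s_got == pytest.approx(s_exp, abs=1e-9)

    def test_sticky_transitions_smooth_isolated_flip(self):
        """One out-of-bed epoch inside an in-bed run is absorbed (p_stay=0.95)."""
        log_start = np.log([0.5, 0.5])
        log_trans = np.log([[0.95, 0.05], [0.05, 0.95]])
        # emissions weakly favour state 0 at t=1 only
        log_lik = np.log(np.array([[0.2, 0.8], [0.6, 0.4], [0.2, 0.8]]))
        path = viterbi(log_start, log_trans, log_lik)
        assert list(path) == [1, 1, 1]


def _separable_features(n, seed=0):
    """In-bed epochs quiet, out-of-bed epochs active; trivially separable."""
    rng = np.random.default_rng(seed)
    in_bed = np.zeros(n, dtype=bool)
    in_bed[n // 4 : 3 * n // 4] = True
    X = np.zeros((n, 3))
    X[:, 0] = np.where(in_bed, 10, 120) + rng.normal(0, 3, n)  # "enmo"
    X[:, 1] = np.where(in_bed, 5, 60) + rng.normal(0, 2, n)  # "sd"
    X[:, 2] = rng.normal(0, 1, n)
    return X, in_bed


class TestWindowModel:
    def test_separable_heldout_accuracy(self):
        X, y = _separable_features(800, seed=1)
        model = fit_window_model(X[:600], y[:600], seed=0)
        acc = (model.forest.predict(X[600:]) == y[600:]).mean()
        assert acc > 0.95

    def test_deterministic_under_seed(self):
        X, y = _separable_features(400, seed=2)
        m1 = fit_window_model(X, y, seed=5)
        m2 = fit_window_model(X, y, seed=5)
        assert (m1.forest.predict_proba(X) == m2.forest.predict_proba(X)).all()
        assert np.allclose(m1.transition, m2.transition)

    def test_transition_rows_stochastic(self):
        X, y = _separable_features(400, seed=3)
        model = fit_window_model(X, y, seed=0)
        assert np.allclose(model.transition.sum(axis=1), 1.0)

    def test_single_class_labels_rejected(self):
        X, _ = _separable_features(100)
        with pytest.raises(ValueError):
            fit_window_model(X, np.ones(100, dtype=bool), seed=0)

    def test_all_out_of_bed_gives_no_windows(self):
        X, y = _separable_features(400, seed=4)
        model = fit_window_model(X, y, seed=0)
        X_out = X[~y][:50]
        times = pd.date_range("2024-01-01", periods=50, freq="30s")
        assert predict_time_in_bed(model, X_out, times) == []

    def test_detected_window_matches_truth(self):
        """Jaccard overlap with the known bed interval exceeds 0.8."""
        X, y = _separable_features(960, seed=5)
        model = fit_window_model(X, y, seed=0)
        times = pd.date_range("2024-01-01 20:00", periods=960, freq="30s")
        ws = predict_time_in_bed(model, X, times)
        ws = merge_windows(ws)
        assert len(ws) >= 1
        w = max(ws, key=lambda w: w.end - w.start)
        t0, t1 = times[240], times[720]  # truth interval
        inter = max(0.0, (min(w.end, t1) - max(w.start, t0)).total_seconds())
        union = (max(w.end, t1) - min(w.start, t0)).total_seconds()
        assert inter / union > 0.8


def _w(start, end):
    return TimeInBedWindow(pd.Timestamp(start), pd.Timestamp(end))


class TestMergeWindows:
    def test_30_min_gap_merged(self):
        out = merge_windows([_w("2024-01-01 22:00", "2024-01-01 23:00"),
                             _w("2024-01-01 23:30", "2024-01-02 06:00")])
        assert len(out) == 1
        assert out[0].start == pd.Timestamp("2024-01-01 22:00")
        assert out[0].end == pd.Timestamp("2024-01-02 06:00")

    def test_61_min_gap_not_merged(self):
        out = merge_windows([_w("2024-01-01 22:00", "2024-01-01 23:00"),
                             _w("2024-01-02 00:01", "2024-01-02 06:00")])
        assert len(out) == 2

    def test_transitive_chain_collapses(self):
        ws = [_w("2024-01-01 20:00", "2024-01-01 21:00"),
              _w("2024-01-01 21:45", "2024-01-01 22:30"),
              _w("2024-01-01 23:15", "2024-01-02 01:00")]
        out = merge_windows(ws)
        assert len(out) == 1
        assert out[0].start == ws[0].start and out[0].end == ws[-1].end

    def test_overlapping_inputs_merged(self):
        out = merge_windows([_w("2024-01-01 22:00", "2024-01-02 01:00"),
                             _w("2024-01-01 23:00", "2024-01-02 02:00")])
        assert len(out) == 1 and out[0].end == pd.Timestamp("2024-01-02 02:00")

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 100)),
                    min_size=0, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_order_invariant(self, raw):
        ws = [_w(pd.Timestamp("2024-01-01") + pd.Timedelta(minutes=s),
                 pd.Timestamp("2024-01-01") + pd.Timedelta(minutes=s + d))
              for s, d in raw]
        once = merge_windows(ws)
        assert merge_windows(once) == once
        assert merge_windows(ws[::-1]) == once


class TestSelectOvernightWindow:
    def test_longest_window_wins_over_nap(self):
        night = _w("2024-01-01 23:00", "2024-01-02 06:00")
        nap = _w("2024-01-02 14:00", "2024-01-02 15:00")
        out = select_overnight_window([night, nap])
        assert out[pd.Timestamp("2024-01-01").date()] == night
        assert out[pd.Timestamp("2024-01-02").date()] == nap

    def test_empty_input(self):
        assert select_overnight_window([]) == {}

    def test_tie_breaks_to_earlier_start(self):
        a = _w("2024-01-01 20:00", "2024-01-01 21:00")
        b = _w("2024-01-01 22:00", "2024-01-01 23:00")
        out = select_overnight_window([a, b])
        assert out[pd.Timestamp("2024-01-01").date()] == a

    def test_midpoint_assignment_across_noon(self):
        # midpoint 11:30 -> belongs to the previous noon-to-noon interval
        w = _w("2024-01-02 09:00", "2024-01-02 14:00")
        out = select_overnight_window([w])
        assert list(out) == [pd.Timestamp("2024-01-01").date()]

    def test_at_most_one_window_per_interval_and_it_is_longest(self):
        ws = [_w("2024-01-01 22:00", "2024-01-02 02:00"),
              _w("2024-01-02 03:30", "2024-01-02 05:00"),
              _w("2024-01-02 13:00", "2024-01-02 13:30")]
        out = select_overnight_window(ws)
        chosen = out[pd.Timestamp("2024-01-01").date()]
        assert chosen == ws[0]
        assert len(out) == 2


@pytest.fixture(scope="module")
def stage_data():
    rng = np.random.default_rng(0)
    feats, labs = {}, {}
    centers = {"W": 100, "N1": 20, "N2": 16, "N3": 14, "R": 25}
    for i in range(10):
        sid = f"S{i}"
        stages = rng.choice(list(centers), size=120)
        X = np.column_stack([
            np.array([centers[s] for s in stages]) + rng.normal(0, 2, 120),
            rng.normal(0, 1, 120),
        ])
        feats[sid], labs[sid] = X, stages.astype(object)
    return feats, labs


class TestRFStageBaseline:

    def test_separable_sleep_wake_kappa(self, stage_data):
        from sleepstagekit.agreement import evaluate_labels
        feats, labs = stage_data
        preds = rf_stage_baseline(feats, labs, k=5, seed=0)
        truth = np.concatenate([labs[s] for s in sorted(labs)])
        pred = np.concatenate([preds[s] for s in sorted(labs)])
        two = {"W": "W", "N1": "S", "N2": "S", "N3": "S", "R": "S"}
        rep = evaluate_labels([two[l] for l in truth], [two[l] for l in pred],
                              ("W", "S"))
        assert rep.kappa > 0.7

    def test_shuffled_labels_give_chance_kappa(self, stage_data):
        from sleepstagekit.agreement import evaluate_labels
        feats, labs = stage_data
        kappas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            shuffled = {s: rng.permutation(l) for s, l in labs.items()}
            preds = rf_stage_baseline(feats, shuffled, k=5, seed=seed)
            truth = np.concatenate([shuffled[s] for s in sorted(labs)])
            pred = np.concatenate([preds[s] for s in sorted(labs)])
            kappas.append(evaluate_labels(truth, pred, "five_class").kappa)
        assert abs(np.mean(kappas)) < 0.05

    def test_deterministic_under_seed(self, stage_data):
        feats, labs = stage_data
        p1 = rf_stage_baseline(feats, labs, k=5, seed=3)
        p2 = rf_stage_baseline(feats, labs, k=5, seed=3)
        for s in p1:
            assert (p1[s] == p2[s]).all()
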