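"""Score-matrix windowing, the LSTM (gradient-checked against finite
differences), and peak picking against a brute-force suppression oracle."""

import numpy as np
import pytest

from ptm.config import RnnConfig
from ptm.intake import (
    BiteLstm,
    BiteSet,
    detect_bites,
    is_positive_sequence,
    predict_probabilities,
    train_rnn,
    window_labels,
    window_scores,
)
from ptm.micromovement import ScoreMatrix
from ptm.signal_io import DegenerateInputError


def _scores(k, rng=None, dt=0.1):
    V = rng.normal(size=(k, 10)) if rng is not None else np.zeros((k, 10))
    times = 0.1 + np.arange(k) * dt
    return ScoreMatrix(V=V, y_mm=np.array(["n"] * k), frame_times=times)


class TestWindowing:
    def test_window_count_formula(self, rng):
        windows, centers = window_scores(_scores(100, rng))
        assert windows.shape == (36, 30, 10)  # floor((100-30)/2)+1
        assert centers.shape == (36,)

    def test_single_window_boundary(self, rng):
        windows, _ = window_scores(_scores(30, rng))
        assert windows.shape[0] == 1

    def test_windows_match_direct_slicing(self, rng):
        sm = _scores(73, rng)
        windows, centers = window_scores(sm)
        for i in range(windows.shape[0]):
            np.testing.assert_array_equal(windows[i], sm.V[i * 2:i * 2 + 30])
        np.testing.assert_allclose(
            centers, (sm.frame_times[np.arange(len(centers)) * 2]
                      + sm.frame_times[np.arange(len(centers)) * 2 + 29]) / 2)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            window_scores(_scores(10, rng))


class TestPositiveRule:
    @pytest.mark.parametrize("seq,expected", [
        ("ppuummdd", True),       # starts p, contains m, ends d
        ("nnuudd", False),        # wrong start, no m
        ("puumd", True),
        ("uummdd", False),        # does not start with p
        ("ppuumm", False),        # does not end with d
        ("ppuudd", False),        # no m event
        ("", False),
    ])
    def test_intake_cycle_rule(self, seq, expected):
        assert is_positive_sequence(list(seq)) is expected

    def test_window_labels_apply_rule_per_window(self):
        lab = list("ppp") + list("u" * 10) + list("m" * 10) + list("d" * 7) + list("n" * 20)
        out = window_labels(lab, k=len(lab), rows=30, step=2)
        expect = [is_positive_sequence(lab[i * 2:i * 2 + 30]) for i in range(len(out))]
        np.testing.assert_array_equal(out, np.array(expect, dtype=float))


class TestLstm:
    def test_gradients_match_finite_differences(self, rng):
        net = BiteLstm(input_dim=3, hidden=4, layers=2, rng=rng)
        X = rng.normal(size=(2, 5, 3))
        y = np.array([1.0, 0.0])
        _, grads = net.loss_and_grads(X, y)
        eps = 1e-6
        for name, p in net.params.items():
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = net.loss_and_grads(X, y)
                flat[idx] = orig - eps
                lm, _ = net.loss_and_grads(X, y)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name].reshape(-1)[idx] == pytest.approx(num, abs=1e-5), name

    def test_learns_separable_sequences(self, rng):
        # positives carry a distinctive temporal pattern in two channels
        def make(n, positive):
            X = rng.normal(scale=0.3, size=(n, 30, 10))
            if positive:
                X[:, :10, 0] += 2.0
                X[:, 10:20, 1] += 2.0
                X[:, 20:, 2] += 2.0
            return X
        Xtr = np.concatenate([make(40, True), make(40, False)])
        ytr = np.concatenate([np.ones(40), np.zeros(40)])
        Xte = np.concatenate([make(20, True), make(20, False)])
        yte = np.concatenate([np.ones(20), np.zeros(20)])
        cfg = RnnConfig(hidden=8, epochs=40, seed=0)
        net, curve = train_rnn(Xtr, ytr, cfg, seed=1)
        acc = ((predict_probabilities(net, Xte) > 0.5) == yte).mean()
        assert acc > 0.9
        assert curve[-1] < curve[0]  # training reduced the loss

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(10, 30, 10))
        with pytest.raises(ValueError):
            train_rnn(X, np.ones(10), RnnConfig(hidden=4, epochs=1))

    def test_training_is_seeded_deterministic(self, rng):
        X = rng.normal(size=(20, 10, 4))
        y = np.array([1.0, 0.0] * 10)
        cfg = RnnConfig(hidden=4, epochs=3, seed=5)
        n1, _ = train_rnn(X, y, cfg)
        n2, _ = train_rnn(X, y, cfg)
        for k in n1.params:
            np.testing.assert_array_equal(n1.params[k], n2.params[k])

    def test_model_roundtrip(self, rng, tmp_path):
        net = BiteLstm(input_dim=10, hidden=4, layers=2, rng=rng)
        X = rng.normal(size=(3, 7, 10))
        net.save(tmp_path / "rnn")
        back = BiteLstm.load(tmp_path / "rnn")
        np.testing.assert_array_equal(back.forward(X), net.forward(X))


def _brute_peaks(p, p_t, min_dist):
    """Exhaustive greedy non-maximum suppression by descending height."""
    thr = [v if v >= p_t else 0.0 for v in p]
    cand = sorted((i for i, v in enumerate(thr) if v > 0),
                  key=lambda i: (-thr[i], i))
    accepted = []
    for i in cand:
        if all(abs(i - j) >= min_dist for j in accepted):
            accepted.append(i)
    return sorted(accepted)


class TestDetectBites:
    def _times(self, n, dt=0.2):
        return 1.6 + np.arange(n) * dt  # p elements at 5 Hz

    def test_all_zero_probabilities_give_empty_set(self):
        out = detect_bites(np.zeros(50), self._times(50))
        assert out.bites == []

    def test_single_plateau_pulse_gives_one_bite_at_first_max(self):
        p = np.zeros(60)
        p[20:25] = 0.95
        out = detect_bites(p, self._times(60))
        assert out.bites == [pytest.approx(self._times(60)[20])]

    def test_close_peaks_suppressed_by_min_distance(self):
        p = np.zeros(60)
        p[20] = 0.93
        p[25] = 0.91  # 1.0 s apart < 3 s minimum
        out = detect_bites(p, self._times(60))
        assert len(out.bites) == 1
        assert out.bites[0] == pytest.approx(self._times(60)[20])

    def test_matches_bruteforce_suppression_on_random_instances(self, rng):
        cfg = RnnConfig()
        for _ in range(200):
            p = rng.uniform(size=40)
            times = self._times(40)
            got = detect_bites(p, times, cfg).bites
            want = [times[i] for i in _brute_peaks(p, cfg.p_t, 15)]
            np.testing.assert_allclose(got, want)

    def test_raising_threshold_never_adds_bites(self, rng):
        p = rng.uniform(size=100)
        times = self._times(100)
        counts = [len(detect_bites(p, times, RnnConfig(p_t=t)).bites)
                  for t in np.linspace(0.05, 0.99, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_trailing_subthreshold_values_are_ignored(self, rng):
        p = np.zeros(50)
        p[10] = 0.95
        times = self._times(80)
        base = detect_bites(p, times[:50]).bites
        padded = detect_bites(np.concatenate([p, np.full(30, 0.5)]), times).bites
        assert base == padded

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            detect_bites(np.array([0.5, 1.2]), self._times(2))

    def test_biteset_requires_increasing_timestamps(self):
        with pytest.raises(ValueError):
            BiteSet(bites=[3.0, 2.0])
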