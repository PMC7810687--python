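"""Bite-moment detection from the temporal evolution of micromovement scores.

Windows of the ``K x 10`` SVM score matrix ``V`` (3 s of signal time, step
0.2 s; 30 rows / step 2 at the default framing) feed a recurrent network —
two stacked LSTM layers followed by a fully connected single sigmoid unit —
that outputs the probability that the window is a food-intake cycle.  A
window is a *positive* training example iff its micromovement label sequence
starts with "p", ends with "d" and contains an "m"; every other window is
negative.  At inference, the probability vector ``p`` is thresholded at
``p_t`` (values below become 0) and bites are the local maxima of ``p``
under a 3 s minimum peak separation; each bite timestamp is the center time
of its peak's window.

The LSTM is implemented here in numpy (forward + backpropagation through
time + Adam); gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import RnnConfig
from .micromovement import ScoreMatrix
from .signal_io import DegenerateInputError


@dataclass
class BiteSet:
    """Ordered detected bite timestamps with the probability trace behind them."""

    bites: list[float]
    probabilities: np.ndarray = field(default_factory=lambda: np.empty(0))
    prob_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.bites = [float(b) for b in self.bites]
        if any(b2 <= b1 for b1, b2 in zip(self.bites, self.bites[1:])):
            raise ValueError("bites must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.bites)


# ---------------------------------------------------------------------------
# windowing of the score matrix
# ---------------------------------------------------------------------------

def window_rows(cfg: RnnConfig, row_rate: float) -> tuple[int, int]:
    """(window, step) in rows of V for the given row rate (rows / second)."""
    rows = int(round(cfg.window_seconds * row_rate))
    step = int(round(cfg.step_seconds * row_rate))
    if rows < 1 or step < 1:
        raise ValueError(f"degenerate window/step rows ({rows}, {step})")
    return rows, step


def window_scores(V: ScoreMatrix, cfg: RnnConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Slice V into ``K' = floor((K - rows) / step) + 1`` windows.

    Returns ``(windows, center_times)``; windows is ``K' x rows x 10``.
    """
    cfg = cfg or RnnConfig()
    rows, step = window_rows(cfg, V.row_rate)
    if V.k < rows:
        raise DegenerateInputError(f"K={V.k} < window rows {rows}")
    kp = (V.k - rows) // step + 1
    idx = np.arange(kp)[:, None] * step + np.arange(rows)[None, :]
    windows = V.V[idx]
    centers = (V.frame_times[idx[:, 0]] + V.frame_times[idx[:, -1]]) / 2.0
    return windows, centers


def is_positive_sequence(labels: Sequence[str]) -> bool:
    """Food-intake-cycle rule: starts with "p", ends with "d", contains "m"."""
    labels = list(labels)
    return len(labels) > 0 and labels[0] == "p" and labels[-1] == "d" and "m" in labels


def window_labels(frame_labels: Sequence[str], k: int, rows: int, step: int) -> np.ndarray:
    """Binary training targets for the K' windows of a meal with GT frame labels."""
    lab = list(frame_labels)
    kp = (k - rows) // step + 1
    return np.array(
        [is_positive_sequence(lab[i * step:i * step + rows]) for i in range(kp)],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# numpy LSTM
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class BiteLstm:
    """Stacked-LSTM binary sequence classifier (numpy).

    Architecture: ``layers`` LSTM layers of ``hidden`` cells each, then a
    fully connected layer with a single sigmoid neuron on the last time
    step's top-layer hidden state.  Gate order in the packed weight matrices
    is (input, forget, cell, output); forget-gate biases start at +1.
    """

    def __init__(self, input_dim: int, hidden: int, layers: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden = hidden
        self.layers = layers
        self.params: dict[str, np.ndarray] = {}
        for l in range(layers):
            d = input_dim if l == 0 else hidden
            k = 1.0 / np.sqrt(hidden)
            self.params[f"Wx{l}"] = rng.uniform(-k, k, size=(d, 4 * hidden))
            self.params[f"Wh{l}"] = rng.uniform(-k, k, size=(hidden, 4 * hidden))
            b = np.zeros(4 * hidden)
            b[hidden:2 * hidden] = 1.0  # forget gate bias
            self.params[f"b{l}"] = b
        self.params["w_out"] = rng.uniform(-0.1, 0.1, size=hidden)
        self.params["b_out"] = np.zeros(1)

    # -- forward -----------------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        """Probabilities for a batch ``X`` of shape (B, T, input_dim)."""
        X = np.asarray(X, dtype=float)
        B, T, _ = X.shape
        H = self.hidden
        caches = []
        inp = X
        for l in range(self.layers):
            Wx, Wh, b = (self.params[f"Wx{l}"], self.params[f"Wh{l}"], self.params[f"b{l}"])
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.empty((B, T, H))
            steps = []
            for t in range(T):
                z = inp[:, t] @ Wx + h @ Wh + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c_prev = c
                c = f * c_prev + i * g
                tc = np.tanh(c)
                h_prev = h
                h = o * tc
                hs[:, t] = h
                if cache:
                    steps.append((i, f, g, o, c_prev, tc, h_prev))
            if cache:
                caches.append((inp, steps))
            inp = hs
        logits = inp[:, -1] @ self.params["w_out"] + self.params["b_out"][0]
        p = _sigmoid(logits)
        if cache:
            return p, (caches, inp[:, -1])
        return p

    # -- loss + gradients --------------------------------------------------
    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean binary cross-entropy and gradients w.r.t. every parameter."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        B, T, _ = X.shape
        H = self.hidden
        p, (caches, h_last) = self.forward(X, cache=True)
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogit = (p - y) / B
        grads["w_out"] = h_last.T @ dlogit
        grads["b_out"] = np.array([dlogit.sum()])

        # gradient on the top layer's hidden states (only last step external)
        dh_out = np.zeros((B, T, H))
        dh_out[:, -1] = dlogit[:, None] * self.params["w_out"][None, :]

        for l in range(self.layers - 1, -1, -1):
            inp, steps = caches[l]
            Wx, Wh = self.params[f"Wx{l}"], self.params[f"Wh{l}"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros(4 * H)
            dx = np.zeros((B, T, inp.shape[2]))
            dh_next = np.zeros((B, H))
            dc = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                i, f, g, o, c_prev, tc, h_prev = steps[t]
                dh = dh_out[:, t] + dh_next
                do = dh * tc
                dc = dc + dh * o * (1 - tc**2)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dz = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                    axis=1,
                )
                dWx += inp[:, t].T @ dz
                dWh += h_prev.T @ dz
                db += dz.sum(axis=0)
                dx[:, t] = dz @ Wx.T
                dh_next = dz @ Wh.T
                dc = dc * f
            grads[f"Wx{l}"] = dWx
            grads[f"Wh{l}"] = dWh
            grads[f"b{l}"] = db
            dh_out = dx  # becomes the external gradient of the layer below
        return loss, grads

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {"input_dim": self.input_dim, "hidden": self.hidden, "layers": self.layers}
        (path / "arch.json").write_text(json.dumps(meta))
        with open(path / "params.pkl", "wb") as fh:
            pickle.dump(self.params, fh)

    @classmethod
    def load(cls, path: str | Path) -> "BiteLstm":
        path = Path(path)
        meta = json.loads((path / "arch.json").read_text())
        net = cls.__new__(cls)
        net.input_dim = meta["input_dim"]
        net.hidden = meta["hidden"]
        net.layers = meta["layers"]
        with open(path / "params.pkl", "rb") as fh:
            net.params = pickle.load(fh)
        return net


def train_rnn(
    windows: np.ndarray,
    labels: np.ndarray,
    cfg: RnnConfig | None = None,
    seed: int | None = None,
) -> tuple[BiteLstm, list[float]]:
    """Train the bite network with Adam on balanced batches.

    Every epoch uses all positives plus an equal-size random draw of
    negatives (balanced negative sampling).  All randomness is seeded.
    Returns the trained net and the per-epoch loss curve.
    """
    cfg = cfg or RnnConfig()
    cfg.validate()
    windows = np.asarray(windows, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = np.flatnonzero(labels > 0.5)
    neg = np.flatnonzero(labels <= 0.5)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("training set must contain both positive and negative windows")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    net = BiteLstm(windows.shape[2], cfg.hidden, cfg.layers, rng)

    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(v) for k, v in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    curve: list[float] = []
    for _ in range(cfg.epochs):
        take_neg = rng.choice(neg, size=min(len(neg), len(pos)), replace=False)
        idx = np.concatenate([pos, take_neg])
        rng.shuffle(idx)
        epoch_loss = 0.0
        nb = 0
        for s in range(0, len(idx), cfg.batch_size):
            batch = idx[s:s + cfg.batch_size]
            loss, grads = net.loss_and_grads(windows[batch], labels[batch])
            step += 1
            for k in net.params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mh = m[k] / (1 - b1**step)
                vh = v[k] / (1 - b2**step)
                net.params[k] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            epoch_loss += loss
            nb += 1
        curve.append(epoch_loss / max(nb, 1))
    return net, curve


def predict_probabilities(net: BiteLstm, windows: np.ndarray, batch: int = 256) -> np.ndarray:
    """Probability vector p over all windows (batched forward pass)."""
    windows = np.asarray(windows, dtype=float)
    return np.concatenate(
        [net.forward(windows[s:s + batch]) for s in range(0, len(windows), batch)]
    ) if len(windows) else np.empty(0)


# ---------------------------------------------------------------------------
# peak picking
# ---------------------------------------------------------------------------

def detect_bites(
    p: np.ndarray,
    prob_times: np.ndarray,
    cfg: RnnConfig | None = None,
) -> BiteSet:
    """Threshold p at ``p_t`` and pick peaks at >= 3 s separation.

    Values below ``p_t`` are zeroed.  Remaining candidates are accepted
    greedily by descending height (plateau ties -> earliest index); any
    candidate closer than ``min_peak_distance_seconds`` to an accepted peak
    is suppressed.  The bite timestamp is the peak window's center time.
    """
    cfg = cfg or RnnConfig()
    p = np.asarray(p, dtype=float)
    prob_times = np.asarray(prob_times, dtype=float)
    if p.shape != prob_times.shape:
        raise ValueError("p and prob_times must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    thr = np.where(p < cfg.p_t, 0.0, p)
    if len(p) >= 2:
        dt = float(np.median(np.diff(prob_times)))
        min_dist = max(1, int(round(cfg.min_peak_distance_seconds / dt)))
    else:
        min_dist = 1
    candidates = np.flatnonzero(thr > 0)
    order = sorted(candidates, key=lambda i: (-thr[i], i))
    accepted: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_dist for j in accepted):
            accepted.append(i)
    accepted.sort()
    return BiteSet(
        bites=[float(prob_times[i]) for i in accepted],
        probabilities=p,
        prob_times=prob_times,
    )
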