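"""From-scratch gated-recurrent-unit surrogate for the conversion response.

The cell follows the bias-free gate equations

    r_t = σ(W_r h_{t−1} + U_r x_t)
    h̃_t = tanh(W (r_t ⊙ h_{t−1}) + U x_t)
    z_t = σ(W_z h_{t−1} + U_z x_t)
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t

with a linear readout of the final hidden state.  Each design run is treated
as a length-1 sequence whose input is the coded factor triple (A, B, C), so
the forward pass is a single cell step from h_0 = 0.  With h_0 = 0 the
recurrent matrices W_r, U_r, W, W_z receive no gradient; they are kept in the
weight container (and in the gradient check, where their gradients are
exactly zero) for fidelity to the cell equations.

Training is full-batch Adam on mean-squared error over standardized targets,
with the study's published hyperparameters: 50 hidden units, global gradient
norm clipped at 0.1, initial learning rate 0.01 dropped by a factor 0.2
every 100 epochs, 150 epochs.  Everything is plain numpy and bitwise
deterministic given (seed, hyperparameters, table).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .design import DesignTable
from .metrics import MetricsReport, score

__all__ = [
    "GruWeights",
    "GruHyperparams",
    "GateTrace",
    "cell_step",
    "forward",
    "init_weights",
    "train",
    "learning_rate_schedule",
    "loss_and_gradients",
    "score_on",
    "DivergenceError",
]

N_INPUT = 3  # coded (A, B, C)


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss; reports the epoch."""


@dataclass
class GruHyperparams:
    """Published training settings for the conversion surrogate."""

    n_hidden: int = 50
    gradient_threshold: float = 0.1
    initial_lr: float = 0.01
    lr_drop_factor: float = 0.2
    lr_drop_period: int = 100
    epochs: int = 150
    seed: int = 0
    use_bias: bool = False  # the published gate equations carry no biases

    def __post_init__(self) -> None:
        if not (0 < self.gradient_threshold <= 1 and 0 < self.lr_drop_factor <= 1):
            raise ValueError("gradient_threshold and lr_drop_factor must be in (0, 1]")
        if min(self.n_hidden, self.lr_drop_period, self.epochs) < 1:
            raise ValueError("n_hidden, lr_drop_period and epochs must be positive")


@dataclass
class GruWeights:
    """Gate/candidate matrices plus linear readout.

    Shapes: W* are (n_hidden, n_hidden) recurrent maps, U* are
    (n_hidden, n_input) input maps; ``readout`` is (n_hidden,) with scalar
    ``offset``.  ``y_mean``/``y_scale`` record the target standardization the
    readout operates under, so predictions are returned in raw % units.
    """

    Wr: np.ndarray
    Ur: np.ndarray
    Wz: np.ndarray
    Uz: np.ndarray
    W: np.ndarray
    U: np.ndarray
    readout: np.ndarray
    offset: float
    br: np.ndarray | None = None
    bz: np.ndarray | None = None
    bh: np.ndarray | None = None
    y_mean: float = 0.0
    y_scale: float = 1.0

    @property
    def n_hidden(self) -> int:
        return self.U.shape[0]

    def __post_init__(self) -> None:
        n = self.n_hidden
        shapes = {
            "Wr": (n, n), "Wz": (n, n), "W": (n, n),
            "Ur": (n, N_INPUT), "Uz": (n, N_INPUT), "U": (n, N_INPUT),
            "readout": (n,),
        }
        for name, want in shapes.items():
            got = getattr(self, name).shape
            if got != want:
                raise ValueError(f"{name} has shape {got}, expected {want}")
        for name in shapes:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_hidden": self.n_hidden,
            "n_input": N_INPUT,
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "offset": self.offset,
        }
        for name in ("Wr", "Ur", "Wz", "Uz", "W", "U", "readout"):
            obj[name] = getattr(self, name).tolist()
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "GruWeights":
        obj = json.loads(Path(path).read_text())
        return cls(
            **{k: np.asarray(obj[k], dtype=float)
               for k in ("Wr", "Ur", "Wz", "Uz", "W", "U", "readout")},
            offset=float(obj["offset"]),
            y_mean=float(obj["y_mean"]),
            y_scale=float(obj["y_scale"]),
        )


@dataclass(frozen=True)
class GateTrace:
    """Intermediate gate activations of one cell step."""

    rt: np.ndarray
    zt: np.ndarray
    h_tilde: np.ndarray
    ht: np.ndarray


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable logistic


def cell_step(x: np.ndarray, h_prev: np.ndarray, w: GruWeights) -> GateTrace:
    """One GRU cell step; returns all gate activations.

    Raises ``ValueError`` on shape mismatch.
    """
    x = np.asarray(x, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if x.shape != (w.U.shape[1],) or h_prev.shape != (w.n_hidden,):
        raise ValueError(
            f"shape mismatch: x {x.shape} (want ({w.U.shape[1]},)), "
            f"h_prev {h_prev.shape} (want ({w.n_hidden},))"
        )
    br = 0.0 if w.br is None else w.br
    bz = 0.0 if w.bz is None else w.bz
    bh = 0.0 if w.bh is None else w.bh
    rt = _sigmoid(w.Wr @ h_prev + w.Ur @ x + br)
    h_tilde = np.tanh(w.W @ (rt * h_prev) + w.U @ x + bh)
    zt = _sigmoid(w.Wz @ h_prev + w.Uz @ x + bz)
    ht = (1.0 - zt) * h_prev + zt * h_tilde
    return GateTrace(rt=rt, zt=zt, h_tilde=h_tilde, ht=ht)


def forward(coded: np.ndarray, w: GruWeights) -> float:
    """Predict conversion % for one coded run: single step from h0=0 + readout."""
    trace = cell_step(np.asarray(coded, dtype=float), np.zeros(w.n_hidden), w)
    return float(
        w.y_mean + w.y_scale * (w.readout @ trace.ht + w.offset)
    )


def _batch_hidden(X: np.ndarray, w: GruWeights) -> tuple[np.ndarray, ...]:
    """Vectorized single-step forward for all runs (h0 = 0 collapses the cell)."""
    z = _sigmoid(X @ w.Uz.T + (0.0 if w.bz is None else w.bz))
    g = np.tanh(X @ w.U.T + (0.0 if w.bh is None else w.bh))
    return z, g, z * g


def predict_batch(X: np.ndarray, w: GruWeights) -> np.ndarray:
    """Predictions (raw %) for an (n, 3) coded matrix."""
    _, _, h = _batch_hidden(np.asarray(X, dtype=float), w)
    return w.y_mean + w.y_scale * (h @ w.readout + w.offset)


def init_weights(hp: GruHyperparams) -> GruWeights:
    """Seeded Glorot-uniform gate/candidate matrices; zero readout.

    The readout starts at zero with zero offset in standardized target space,
    i.e. the initial prediction is the training-set mean.
    """
    rng = np.random.default_rng(hp.seed)
    n = hp.n_hidden

    def glorot(fan_out: int, fan_in: int) -> np.ndarray:
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, (fan_out, fan_in))

    kw: dict = {}
    if hp.use_bias:
        kw = {"br": np.zeros(n), "bz": np.zeros(n), "bh": np.zeros(n)}
    return GruWeights(
        Wr=glorot(n, n), Ur=glorot(n, N_INPUT),
        Wz=glorot(n, n), Uz=glorot(n, N_INPUT),
        W=glorot(n, n), U=glorot(n, N_INPUT),
        readout=np.zeros(n), offset=0.0, **kw,
    )


def learning_rate_schedule(hp: GruHyperparams) -> np.ndarray:
    """Per-epoch step-decay schedule: lr0 · drop^⌊epoch/period⌋."""
    epochs = np.arange(hp.epochs)
    return hp.initial_lr * hp.lr_drop_factor ** (epochs // hp.lr_drop_period)


# parameters that receive gradient through the length-1 forward pass
_TRAINED = ("U", "Uz", "readout")
# recurrent parameters whose gradient is identically zero when h0 = 0
_FROZEN = ("Wr", "Ur", "Wz", "W")


def loss_and_gradients(
    w: GruWeights, X: np.ndarray, y_std: np.ndarray
) -> tuple[float, dict[str, np.ndarray], float]:
    """MSE loss in standardized target space and its analytic gradients.

    Returns (loss, gradients keyed by parameter name incl. the zero-gradient
    recurrent matrices, offset gradient).
    """
    n = len(y_std)
    z, g, h = _batch_hidden(X, w)
    pred = h @ w.readout + w.offset
    err = pred - y_std
    loss = float(np.mean(err**2))
    e = 2.0 * err / n
    grads: dict[str, np.ndarray] = {
        "readout": h.T @ e,
    }
    dh = np.outer(e, w.readout)
    dz = dh * g
    dg = dh * z
    da = dz * z * (1.0 - z)
    db = dg * (1.0 - g * g)
    grads["Uz"] = da.T @ X
    grads["U"] = db.T @ X
    if w.bz is not None:
        grads["bz"] = da.sum(axis=0)
    if w.bh is not None:
        grads["bh"] = db.sum(axis=0)
    if w.br is not None:
        grads["br"] = np.zeros_like(w.br)  # no gradient path with h0 = 0
    for name in _FROZEN:
        grads[name] = np.zeros_like(getattr(w, name))
    d_offset = float(np.sum(e))
    return loss, grads, d_offset


def _clip_global(
    grads: dict[str, np.ndarray], d_offset: float, threshold: float
) -> tuple[dict[str, np.ndarray], float, float]:
    """Global L2-norm gradient clipping across all parameters."""
    sq = d_offset**2 + sum(float(np.sum(v * v)) for v in grads.values())
    norm = float(np.sqrt(sq))
    if norm > threshold:
        scale = threshold / norm
        grads = {k: v * scale for k, v in grads.items()}
        d_offset *= scale
    return grads, d_offset, norm


def train(
    table: DesignTable, hp: GruHyperparams
) -> tuple[GruWeights, pd.DataFrame]:
    """Train the surrogate on a design table with responses.

    Full-batch Adam on MSE over standardized responses; global-norm gradient
    clipping at ``hp.gradient_threshold``; step-decay learning-rate schedule.
    Returns the trained weights and a per-epoch trace (epoch, lr, loss), with
    loss reported in raw %² units.

    Raises
    ------
    DivergenceError
        if the loss becomes non-finite.
    """
    y = table.responses
    if len(y) < 2:
        raise ValueError("need at least 2 runs with responses to train")
    X = table.coded
    w = init_weights(hp)
    w.y_mean = float(np.mean(y))
    w.y_scale = float(np.std(y)) or 1.0
    y_std = (y - w.y_mean) / w.y_scale

    lrs = learning_rate_schedule(hp)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    trained = list(_TRAINED) + (["bz", "bh"] if hp.use_bias else [])
    m = {k: np.zeros_like(getattr(w, k)) for k in trained}
    v = {k: np.zeros_like(getattr(w, k)) for k in trained}
    m_off = v_off = 0.0
    trace = []
    for epoch in range(hp.epochs):
        loss, grads, d_off = loss_and_gradients(w, X, y_std)
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        trace.append((epoch, lrs[epoch], loss * w.y_scale**2))
        grads, d_off, _ = _clip_global(grads, d_off, hp.gradient_threshold)
        t = epoch + 1
        c1, c2 = 1.0 - beta1**t, 1.0 - beta2**t
        for k in trained:
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
            getattr(w, k)[...] -= lrs[epoch] * (m[k] / c1) / (np.sqrt(v[k] / c2) + eps)
        m_off = beta1 * m_off + (1 - beta1) * d_off
        v_off = beta2 * v_off + (1 - beta2) * d_off**2
        w.offset -= lrs[epoch] * (m_off / c1) / (np.sqrt(v_off / c2) + eps)
    trace_df = pd.DataFrame(trace, columns=["epoch", "lr", "loss"])
    return w, trace_df


def score_on(table: DesignTable, w: GruWeights) -> tuple[MetricsReport, np.ndarray]:
    """Predict every run of the table and score against its responses."""
    pred = predict_batch(table.coded, w)
    return score(table.responses, pred), pred
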