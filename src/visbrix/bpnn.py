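"""Three-layer back-propagation network with dynamic learning-rate decay.

A from-scratch fully-connected network with one logistic-sigmoid hidden
layer, trained by full-batch gradient descent on an MSE loss. The output
layer is sigmoid for 3-grade classification (one-hot targets) or linear for
°Brix regression. The learning rate follows one of four nonlinear decay
schedules (exponential, cosine, Gaussian, sigmoid) or stays fixed:

    exponential: eta0 * (1 - t/T)**p
    cosine:      0.5 * eta0 * (1 + cos(pi * t / T))
    gaussian:    eta0 * exp(-t**2 / (2 * gamma**2))
    sigmoid:     eta0 / (1 + exp(gamma * (t - T/2)))

All four are non-increasing on [0, T]: a large rate explores early, a small
rate stabilises late training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LRSchedule",
    "BPNNModel",
    "TrainingTrace",
    "DivergenceError",
    "hidden_size",
    "lr_at",
    "init_bpnn",
    "forward",
    "train_gd",
    "sse_loss",
    "predict_grade",
    "one_hot",
    "Standardizer",
]

SCHEDULE_KINDS = ("fixed", "exponential", "cosine", "gaussian", "sigmoid")


class DivergenceError(RuntimeError):
    pass


@dataclass
class LRSchedule:
    """Learning-rate schedule. ``gamma`` defaults to T/3 for the gaussian
    kind and 10/T for the sigmoid kind when left unset; ``p`` (exponential
    exponent) defaults to 2 (concave decay)."""

    kind: str = "gaussian"
    eta0: float = 0.001
    T: int = 3000
    p: float = 2.0
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCHEDULE_KINDS:
            raise ValueError(f"unknown schedule {self.kind!r}; kinds: {SCHEDULE_KINDS}")
        # eta0 = 0 is admitted as the degenerate "no update" rate
        if self.eta0 < 0 or self.T < 1 or self.p <= 0:
            raise ValueError("require eta0 >= 0, T >= 1, p > 0")
        if self.gamma is None:
            self.gamma = self.T / 3.0 if self.kind == "gaussian" else 10.0 / self.T
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def lr_at(schedule: LRSchedule, t: float) -> float:
    """Learning rate at iteration t in [0, T]."""
    if not 0 <= t <= schedule.T:
        raise ValueError(f"iteration {t} outside [0, {schedule.T}]")
    eta0, T, g = schedule.eta0, schedule.T, schedule.gamma
    if schedule.kind == "fixed":
        return eta0
    if schedule.kind == "exponential":
        return eta0 * (1.0 - t / T) ** schedule.p
    if schedule.kind == "cosine":
        return 0.5 * eta0 * (1.0 + np.cos(t * np.pi / T))
    if schedule.kind == "gaussian":
        return eta0 * float(np.exp(-(t**2) / (2.0 * g**2)))
    # sigmoid decay: flipped sign relative to the textbook logistic so the
    # rate decreases with t, matching the other three strategies
    return eta0 / (1.0 + float(np.exp(g * (t - T / 2.0))))


def hidden_size(m: int, n: int, a: int) -> int:
    """Empirical hidden-layer size h = round(sqrt(m + n)) + a, a in [1, 10]."""
    if m < 1 or n < 1:
        raise ValueError("layer sizes must be >= 1")
    if not 1 <= a <= 10:
        raise ValueError(f"adjustable constant a must lie in [1, 10], got {a}")
    return int(round(np.sqrt(m + n))) + a


@dataclass
class BPNNModel:
    """Weights/thresholds of the (m, h, n) network. ``hidden_weights`` is
    m x h, ``output_weights`` h x n; thresholds are the layer biases."""

    hidden_weights: np.ndarray
    hidden_thresholds: np.ndarray
    output_weights: np.ndarray
    output_thresholds: np.ndarray
    output_activation: str = "sigmoid"  # "sigmoid" | "linear"

    def __post_init__(self) -> None:
        m, h = self.hidden_weights.shape
        h2, n = self.output_weights.shape
        if h != h2 or self.hidden_thresholds.shape != (h,) or \
                self.output_thresholds.shape != (n,):
            raise ValueError("inconsistent weight/threshold shapes")
        if self.output_activation not in ("sigmoid", "linear"):
            raise ValueError("output_activation must be 'sigmoid' or 'linear'")

    @property
    def topology(self) -> tuple[int, int, int]:
        m, h = self.hidden_weights.shape
        return m, h, self.output_weights.shape[1]

    def copy(self) -> "BPNNModel":
        return BPNNModel(
            self.hidden_weights.copy(), self.hidden_thresholds.copy(),
            self.output_weights.copy(), self.output_thresholds.copy(),
            self.output_activation,
        )


@dataclass
class TrainingTrace:
    mse: np.ndarray
    learning_rate: np.ndarray

    @property
    def epochs(self) -> int:
        return self.mse.size


def init_bpnn(
    m: int, h: int, n: int, output_activation: str = "sigmoid", seed: int = 0
) -> BPNNModel:
    """Weights uniform on [-0.5, 0.5], thresholds zero; deterministic per seed."""
    if min(m, h, n) < 1:
        raise ValueError("layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    return BPNNModel(
        hidden_weights=rng.uniform(-0.5, 0.5, (m, h)),
        hidden_thresholds=np.zeros(h),
        output_weights=rng.uniform(-0.5, 0.5, (h, n)),
        output_thresholds=np.zeros(n),
        output_activation=output_activation,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(model: BPNNModel, inputs: np.ndarray) -> np.ndarray:
    """Network outputs for a batch of feature vectors (width m)."""
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    m = model.hidden_weights.shape[0]
    if x.shape[1] != m:
        raise ValueError(f"input width {x.shape[1]} != input layer size {m}")
    hidden = _sigmoid(x @ model.hidden_weights + model.hidden_thresholds)
    z = hidden @ model.output_weights + model.output_thresholds
    return _sigmoid(z) if model.output_activation == "sigmoid" else z


def mse_loss(model: BPNNModel, inputs: np.ndarray, targets: np.ndarray) -> float:
    pred = forward(model, inputs)
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    if t.shape[0] == 1 and pred.shape[0] != 1:
        t = t.T
    return float(np.mean((pred - t) ** 2))


def sse_loss(model: BPNNModel, inputs: np.ndarray, targets: np.ndarray) -> float:
    """Training objective: the classic batch error E = 0.5 * sum((y - t)**2).

    The per-epoch trace reports the MSE (mean over elements) for
    comparability across sample counts, but weight updates follow the
    summed-error delta rule, under which the conventional small learning
    rates (1e-3) drive full-batch training at practical speed.
    """
    pred = forward(model, inputs)
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    if t.shape[0] == 1 and pred.shape[0] != 1:
        t = t.T
    return 0.5 * float(np.sum((pred - t) ** 2))


def gradients(
    model: BPNNModel, inputs: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradient of the batch error E = 0.5 * sum((y - t)**2)."""
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    if t.shape[0] == 1 and x.shape[0] != 1:
        t = t.T
    hidden = _sigmoid(x @ model.hidden_weights + model.hidden_thresholds)
    z2 = hidden @ model.output_weights + model.output_thresholds
    out = _sigmoid(z2) if model.output_activation == "sigmoid" else z2
    delta_out = out - t
    if model.output_activation == "sigmoid":
        delta_out = delta_out * out * (1.0 - out)
    g_w2 = hidden.T @ delta_out
    g_b2 = delta_out.sum(axis=0)
    delta_hidden = (delta_out @ model.output_weights.T) * hidden * (1.0 - hidden)
    g_w1 = x.T @ delta_hidden
    g_b1 = delta_hidden.sum(axis=0)
    return g_w1, g_b1, g_w2, g_b2


def train_gd(
    model: BPNNModel,
    features: np.ndarray,
    targets: np.ndarray,
    schedule: LRSchedule,
    epochs: int | None = None,
) -> tuple[BPNNModel, TrainingTrace]:
    """Full-batch gradient descent; epoch t uses rate lr_at(schedule, t).

    Targets are one-hot rows (classification) or scalars (regression); the
    caller standardizes features. Returns a fresh model and the per-epoch
    training-MSE / learning-rate trace.
    """
    model = model.copy()
    x = np.atleast_2d(np.asarray(features, dtype=float))
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    if t.shape[0] == 1 and x.shape[0] != 1:
        t = t.T
    if t.shape[0] != x.shape[0]:
        raise ValueError("features and targets must have equal sample counts")
    if epochs is None:
        epochs = schedule.T
    mse_trace = np.empty(epochs)
    lr_trace = np.empty(epochs)
    for epoch in range(1, epochs + 1):
        lr = lr_at(schedule, min(epoch, schedule.T))
        g_w1, g_b1, g_w2, g_b2 = gradients(model, x, t)
        loss = mse_loss(model, x, t)
        if not np.isfinite(loss):
            raise DivergenceError(f"training diverged (NaN/inf loss) at epoch {epoch}")
        mse_trace[epoch - 1] = loss
        lr_trace[epoch - 1] = lr
        model.hidden_weights -= lr * g_w1
        model.hidden_thresholds -= lr * g_b1
        model.output_weights -= lr * g_w2
        model.output_thresholds -= lr * g_b2
    return model, TrainingTrace(mse=mse_trace, learning_rate=lr_trace)


def predict_grade(model: BPNNModel, features: np.ndarray) -> np.ndarray:
    """Argmax grade (1-based) over the 3 sigmoid outputs; ties break toward
    the lower (better) grade index."""
    if model.output_activation != "sigmoid":
        raise ValueError("predict_grade requires a classification (sigmoid) model")
    out = forward(model, features)
    return np.argmax(out, axis=1) + 1


def one_hot(grades: np.ndarray, n_classes: int = 3) -> np.ndarray:
    g = np.asarray(grades, dtype=int)
    if np.any((g < 1) | (g > n_classes)):
        raise ValueError(f"grades must lie in 1..{n_classes}")
    out = np.zeros((g.size, n_classes))
    out[np.arange(g.size), g - 1] = 1.0
    return out


@dataclass
class Standardizer:
    """Zero-mean, unit-variance column scaling fit on the training split."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sd: np.ndarray = field(default_factory=lambda: np.ones(0))

    def fit(self, x: np.ndarray) -> "Standardizer":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self.mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.ones(x.shape[1])
        self.sd = np.where(sd == 0, 1.0, sd)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(x, dtype=float)) - self.mean) / self.sd

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) * self.sd + self.mean
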