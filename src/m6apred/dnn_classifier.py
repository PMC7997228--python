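"""Feed-forward neural network classifier and the binary evaluation suite.

The network is a fully connected stack
input -> hidden_1 -> dropout -> hidden_2 -> dropout [-> hidden_3 -> dropout]
-> 1-unit sigmoid output, trained by mini-batch backpropagation on the mean
binary cross-entropy.  Activations, optimizers and weight initializers are
implemented natively (no deep-learning framework dependency) under their
conventional names, with the conventional default hyper-parameters of each
update rule.

Evaluation: confusion-based Sn/Sp/ACC/MCC plus rank-based (Mann-Whitney)
AUC, and a fold-safe stratified cross-validation driver that refits all
label-dependent preprocessing inside each training fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.stats import rankdata

from m6apred.encoders import FeatureMatrix
from m6apred.sequence_io import FoldAssignment

__all__ = [
    "ACTIVATIONS",
    "OPTIMIZERS",
    "INITIALIZERS",
    "DnnConfig",
    "TrainedDnn",
    "MetricsReport",
    "build_dnn",
    "train_dnn",
    "predict_proba",
    "compute_metrics",
    "cross_validate",
    "mean_report",
]

# ---------------------------------------------------------------------------
# activations: name -> (f, f') evaluated on the pre-activation


_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _selu(x):
    return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))


def _selu_grad(x):
    return _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_grad(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softsign(x):
    return x / (1.0 + np.abs(x))


def _softsign_grad(x):
    return 1.0 / (1.0 + np.abs(x)) ** 2


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    return (x > 0).astype(float)


def _tanh_grad(x):
    return 1.0 - np.tanh(x) ** 2


def _hard_sigmoid(x):
    return np.clip(0.2 * x + 0.5, 0.0, 1.0)


def _hard_sigmoid_grad(x):
    return np.where((x > -2.5) & (x < 2.5), 0.2, 0.0)


ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "elu": (_elu, _elu_grad),
    "selu": (_selu, _selu_grad),
    "softplus": (_softplus, _softplus_grad),
    "softsign": (_softsign, _softsign_grad),
    "relu": (_relu, _relu_grad),
    "tanh": (np.tanh, _tanh_grad),
    "hard_sigmoid": (_hard_sigmoid, _hard_sigmoid_grad),
}


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable


# ---------------------------------------------------------------------------
# optimizers


class _Optimizer:
    """Per-parameter adaptive update rule; state lazily keyed by parameter id."""

    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0
        self.state: dict[int, dict[str, np.ndarray]] = {}

    def _slot(self, key: int, like: np.ndarray, names: tuple[str, ...]):
        if key not in self.state:
            self.state[key] = {n: np.zeros_like(like) for n in names}
        return self.state[key]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for key, (p, g) in enumerate(zip(params, grads)):
            self._update(key, p, g)

    def _update(self, key: int, p: np.ndarray, g: np.ndarray) -> None:
        raise NotImplementedError


class _SGD(_Optimizer):
    def _update(self, key, p, g):
        p -= self.lr * g


class _RMSprop(_Optimizer):
    rho, eps = 0.9, 1e-7

    def _update(self, key, p, g):
        s = self._slot(key, p, ("a",))
        s["a"] = self.rho * s["a"] + (1 - self.rho) * g**2
        p -= self.lr * g / (np.sqrt(s["a"]) + self.eps)


class _Adagrad(_Optimizer):
    eps = 1e-7

    def _update(self, key, p, g):
        s = self._slot(key, p, ("a",))
        s["a"] += g**2
        p -= self.lr * g / (np.sqrt(s["a"]) + self.eps)


class _Adadelta(_Optimizer):
    rho, eps = 0.95, 1e-7

    def _update(self, key, p, g):
        s = self._slot(key, p, ("a", "d"))
        s["a"] = self.rho * s["a"] + (1 - self.rho) * g**2
        update = np.sqrt(s["d"] + self.eps) / np.sqrt(s["a"] + self.eps) * g
        s["d"] = self.rho * s["d"] + (1 - self.rho) * update**2
        p -= self.lr * update


class _Adam(_Optimizer):
    b1, b2, eps = 0.9, 0.999, 1e-7

    def _update(self, key, p, g):
        s = self._slot(key, p, ("m", "v"))
        s["m"] = self.b1 * s["m"] + (1 - self.b1) * g
        s["v"] = self.b2 * s["v"] + (1 - self.b2) * g**2
        mhat = s["m"] / (1 - self.b1**self.t)
        vhat = s["v"] / (1 - self.b2**self.t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _Adamax(_Optimizer):
    b1, b2, eps = 0.9, 0.999, 1e-7

    def _update(self, key, p, g):
        s = self._slot(key, p, ("m", "u"))
        s["m"] = self.b1 * s["m"] + (1 - self.b1) * g
        s["u"] = np.maximum(self.b2 * s["u"], np.abs(g))
        p -= self.lr / (1 - self.b1**self.t) * s["m"] / (s["u"] + self.eps)


class _Nadam(_Optimizer):
    b1, b2, eps = 0.9, 0.999, 1e-7

    def _update(self, key, p, g):
        s = self._slot(key, p, ("m", "v"))
        s["m"] = self.b1 * s["m"] + (1 - self.b1) * g
        s["v"] = self.b2 * s["v"] + (1 - self.b2) * g**2
        mhat = s["m"] / (1 - self.b1 ** (self.t + 1))
        vhat = s["v"] / (1 - self.b2**self.t)
        m_bar = self.b1 * mhat + (1 - self.b1) * g / (1 - self.b1**self.t)
        p -= self.lr * m_bar / (np.sqrt(vhat) + self.eps)


OPTIMIZERS: dict[str, type[_Optimizer]] = {
    "SGD": _SGD,
    "RMSprop": _RMSprop,
    "Adagrad": _Adagrad,
    "Adadelta": _Adadelta,
    "Adam": _Adam,
    "Adamax": _Adamax,
    "Nadam": _Nadam,
}


# ---------------------------------------------------------------------------
# initializers


def _init_weight(name: str, fan_in: int, fan_out: int, rng: np.random.Generator):
    shape = (fan_in, fan_out)
    if name == "uniform":
        return rng.uniform(-0.05, 0.05, shape)
    if name == "normal":
        return rng.normal(0.0, 0.05, shape)
    if name == "lecun_uniform":
        limit = np.sqrt(3.0 / fan_in)
        return rng.uniform(-limit, limit, shape)
    if name == "glorot_uniform":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, shape)
    if name == "glorot_normal":
        return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), shape)
    if name == "he_normal":
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
    if name == "he_uniform":
        limit = np.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, shape)
    raise ValueError(
        f"unknown kernel_initializer '{name}'; valid: {sorted(INITIALIZERS)}"
    )


INITIALIZERS = (
    "uniform",
    "normal",
    "lecun_uniform",
    "glorot_uniform",
    "glorot_normal",
    "he_normal",
    "he_uniform",
)


# ---------------------------------------------------------------------------
# configuration and model containers


@dataclass
class DnnConfig:
    """Hyper-parameter assignment for one network."""

    layers: int = 2
    hidden_1: int = 128
    hidden_2: int = 64
    hidden_3: int | None = None
    activation: str = "relu"
    optimizer: str = "Adam"
    learning_rate: float = 0.001
    kernel_initializer: str = "glorot_uniform"
    dropout: float = 0.3
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layers not in (2, 3):
            raise ValueError("layers must be 2 or 3")
        if self.layers == 3 and self.hidden_3 is None:
            raise ValueError("hidden_3 must be set when layers=3")
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation '{self.activation}'; valid: {sorted(ACTIVATIONS)}"
            )
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer '{self.optimizer}'; valid: {sorted(OPTIMIZERS)}"
            )
        if self.kernel_initializer not in INITIALIZERS:
            raise ValueError(
                f"unknown kernel_initializer '{self.kernel_initializer}'; "
                f"valid: {sorted(INITIALIZERS)}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def hidden_sizes(self) -> list[int]:
        sizes = [self.hidden_1, self.hidden_2]
        if self.layers == 3:
            sizes.append(int(self.hidden_3))
        return sizes

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, obj: dict) -> "DnnConfig":
        return cls(**obj)


@dataclass
class TrainedDnn:
    """Weights/biases per layer plus the config that produced them.

    The last layer is always a single sigmoid unit; hidden layers use
    ``config.activation``.
    """

    config: DnnConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    loss_trace: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def save(self, directory: str | Path) -> None:
        """Persist as architecture JSON plus plain-text weight arrays."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "architecture.json").write_text(
            json.dumps(
                {
                    "config": self.config.to_dict(),
                    "n_layers": len(self.weights),
                    "loss_trace": self.loss_trace,
                }
            )
        )
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            np.savetxt(directory / f"weight_{i}.tsv", W, delimiter="\t")
            np.savetxt(directory / f"bias_{i}.tsv", b[None, :], delimiter="\t")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedDnn":
        directory = Path(directory)
        arch = json.loads((directory / "architecture.json").read_text())
        weights, biases = [], []
        for i in range(arch["n_layers"]):
            W = np.loadtxt(directory / f"weight_{i}.tsv", delimiter="\t", ndmin=2)
            b = np.loadtxt(directory / f"bias_{i}.tsv", delimiter="\t", ndmin=2)[0]
            weights.append(W)
            biases.append(b)
        return cls(
            config=DnnConfig.from_dict(arch["config"]),
            weights=weights,
            biases=biases,
            loss_trace=arch["loss_trace"],
        )


def build_dnn(config: DnnConfig, input_dim: int) -> TrainedDnn:
    """Initialize an untrained network with the configured initializer/seed."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    sizes = [input_dim] + config.hidden_sizes + [1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(_init_weight(config.kernel_initializer, fan_in, fan_out, rng))
        biases.append(np.zeros(fan_out))
    return TrainedDnn(config=config, weights=weights, biases=biases)


def _forward(
    model: TrainedDnn,
    X: np.ndarray,
    dropout_rng: np.random.Generator | None = None,
):
    """Forward pass; inverted dropout after each hidden layer when training."""
    act, _ = ACTIVATIONS[model.config.activation]
    rate = model.config.dropout
    pre, post, masks = [], [X], []
    a = X
    n_hidden = len(model.weights) - 1
    for l in range(n_hidden):
        z = a @ model.weights[l] + model.biases[l]
        a = act(z)
        if dropout_rng is not None and rate > 0:
            mask = (dropout_rng.random(a.shape) >= rate) / (1.0 - rate)
            a = a * mask
        else:
            mask = None
        pre.append(z)
        post.append(a)
        masks.append(mask)
    z_out = a @ model.weights[-1] + model.biases[-1]
    y_hat = _sigmoid(z_out).ravel()
    return y_hat, pre, post, masks


def train_dnn(
    model: TrainedDnn,
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    config: DnnConfig | None = None,
) -> TrainedDnn:
    """Train in place by mini-batch backpropagation on binary cross-entropy.

    Shuffles each epoch and records the mean epoch loss in ``loss_trace``.
    Raises if the loss becomes non-finite (reporting the epoch) or X is
    empty.
    """
    config = config or model.config
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xv.size == 0:
        raise ValueError("empty training matrix")
    if Xv.shape[1] != model.input_dim:
        raise ValueError(
            f"X has {Xv.shape[1]} columns, model expects {model.input_dim}"
        )
    n = Xv.shape[0]
    _, act_grad = ACTIVATIONS[config.activation]
    opt = OPTIMIZERS[config.optimizer](config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)  # decoupled from init stream

    eps = 1e-12
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = Xv[idx], y[idx]
            y_hat, pre, post, masks = _forward(model, xb, dropout_rng=rng)
            p = np.clip(y_hat, eps, 1 - eps)
            loss = -np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p))
            epoch_losses.append(loss * len(idx))

            # output delta for sigmoid + BCE
            delta = ((y_hat - yb) / len(idx))[:, None]
            grads_w = [np.zeros_like(w) for w in model.weights]
            grads_b = [np.zeros_like(b) for b in model.biases]
            grads_w[-1] = post[-1].T @ delta
            grads_b[-1] = delta.sum(axis=0)
            back = delta @ model.weights[-1].T
            for l in range(len(model.weights) - 2, -1, -1):
                if masks[l] is not None:
                    back = back * masks[l]
                back = back * act_grad(pre[l])
                grads_w[l] = post[l].T @ back
                grads_b[l] = back.sum(axis=0)
                if l > 0:
                    back = back @ model.weights[l].T
            opt.step(model.weights + model.biases, grads_w + grads_b)

        mean_loss = float(np.sum(epoch_losses) / n)
        if not np.isfinite(mean_loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}")
        model.loss_trace.append(mean_loss)
    return model


def predict_proba(model: TrainedDnn, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Sigmoid output probabilities; dropout disabled."""
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[None, :]
    if Xv.shape[1] != model.input_dim:
        raise ValueError(
            f"X has {Xv.shape[1]} columns, model expects {model.input_dim}"
        )
    y_hat, *_ = _forward(model, Xv, dropout_rng=None)
    return y_hat


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    """Confusion counts plus Sn/Sp/ACC/MCC/AUC at a fixed threshold."""

    TP: int
    TN: int
    FP: int
    FN: int
    Sn: float
    Sp: float
    ACC: float
    MCC: float
    AUC: float
    threshold: float = 0.5

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney U statistic with mid-ranked ties."""
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Confusion at ``threshold`` (score >= threshold is positive) + AUC.

    MCC uses the standard four-factor square-root denominator and is
    defined as 0 whenever a confusion margin is 0.  With single-class
    ``y_true`` the undefined quantities are NaN (with a warning).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(y_true) != len(scores):
        raise ValueError("y_true and scores differ in length")
    pred = (scores >= threshold).astype(int)
    TP = int(np.sum((pred == 1) & (y_true == 1)))
    TN = int(np.sum((pred == 0) & (y_true == 0)))
    FP = int(np.sum((pred == 1) & (y_true == 0)))
    FN = int(np.sum((pred == 0) & (y_true == 1)))

    if TP + FN == 0 or TN + FP == 0:
        warnings.warn("single-class y_true: Sn or Sp (and AUC) undefined", stacklevel=2)
    Sn = TP / (TP + FN) if TP + FN > 0 else float("nan")
    Sp = TN / (TN + FP) if TN + FP > 0 else float("nan")
    ACC = (TP + TN) / len(y_true)
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    MCC = (TP * TN - FP * FN) / np.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(
        TP=TP,
        TN=TN,
        FP=FP,
        FN=FN,
        Sn=Sn,
        Sp=Sp,
        ACC=float(ACC),
        MCC=float(MCC),
        AUC=_auc_rank(y_true, scores),
        threshold=threshold,
    )


def mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Entry-wise fold-mean of metric values (counts summed)."""
    return MetricsReport(
        TP=sum(r.TP for r in reports),
        TN=sum(r.TN for r in reports),
        FP=sum(r.FP for r in reports),
        FN=sum(r.FN for r in reports),
        Sn=float(np.mean([r.Sn for r in reports])),
        Sp=float(np.mean([r.Sp for r in reports])),
        ACC=float(np.mean([r.ACC for r in reports])),
        MCC=float(np.mean([r.MCC for r in reports])),
        AUC=float(np.mean([r.AUC for r in reports])),
        threshold=reports[0].threshold,
    )


FoldDataHook = Callable[
    [np.ndarray, np.ndarray],
    tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
]


def cross_validate(
    X: FeatureMatrix | np.ndarray | None,
    y: np.ndarray,
    config: DnnConfig,
    folds: FoldAssignment,
    fold_data_hook: FoldDataHook | None = None,
    threshold: float = 0.5,
    pooled: bool = False,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified CV of the network; label-dependent steps refit per fold.

    ``fold_data_hook(train_idx, test_idx)`` must return
    ``(X_train, y_train, X_test, y_test)`` and is where fold-safe refitting
    of propensity matrices and feature selection happens; when omitted, the
    hook is a plain row split of ``X``.

    Returns per-fold reports and their mean (or a single pooled report over
    concatenated held-out predictions when ``pooled``).
    """
    y = np.asarray(y, dtype=float)
    if fold_data_hook is None:
        if X is None:
            raise ValueError("either X or fold_data_hook is required")
        Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)

        def fold_data_hook(train_idx, test_idx):  # noqa: F811 - default hook
            return Xv[train_idx], y[train_idx], Xv[test_idx], y[test_idx]

    reports: list[MetricsReport] = []
    pooled_y, pooled_scores = [], []
    for fold_i, (train_idx, test_idx) in enumerate(folds):
        try:
            X_tr, y_tr, X_te, y_te = fold_data_hook(train_idx, test_idx)
            model = build_dnn(config, X_tr.shape[1])
            train_dnn(model, X_tr, y_tr, config)
            scores = predict_proba(model, X_te)
        except Exception as exc:
            raise RuntimeError(f"cross-validation failed in fold {fold_i}") from exc
        reports.append(compute_metrics(y_te, scores, threshold))
        pooled_y.append(y_te)
        pooled_scores.append(scores)

    if pooled:
        summary = compute_metrics(
            np.concatenate(pooled_y), np.concatenate(pooled_scores), threshold
        )
    else:
        summary = mean_report(reports)
    return reports, summary
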