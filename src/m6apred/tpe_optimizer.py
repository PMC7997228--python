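"""Native tree-structured Parzen estimator over a mixed search space.

The optimizer minimizes a loss (here: 1 - mean CV accuracy).  After a
startup phase of prior draws, the trial history is split at the
gamma-quantile of observed losses into a "good" and a "bad" set; per
dimension, kernel (continuous/integer) or Laplace-smoothed categorical
(choice) densities l and g are built from the two sets, candidates are
drawn from l, and the candidate maximizing l/g — equivalent to maximizing
expected improvement — is evaluated next.

The space is tree-structured: a dimension may be conditional on another
dimension's value (e.g. hidden_3 exists only when layers=3) and then
contributes to densities only for trials where it was active.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "Dimension",
    "SearchSpace",
    "Trial",
    "TrialHistory",
    "default_search_space",
    "tpe_suggest",
    "optimize",
]


@dataclass(frozen=True)
class Dimension:
    """One hyper-parameter domain.

    kind: "uniform" (continuous), "loguniform" (continuous, log-scale
    sampling and modeling), "int" (integer range, inclusive), or "choice"
    (categorical over ``choices``).  ``condition`` is an optional
    (dimension-name, value) pair; the dimension is active only in
    configurations where that dimension equals the value.
    """

    name: str
    kind: str
    low: float | None = None
    high: float | None = None
    choices: tuple | None = None
    condition: tuple[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.kind in ("uniform", "loguniform", "int"):
            if self.low is None or self.high is None or self.low >= self.high:
                raise ValueError(f"dimension '{self.name}': invalid bounds")
            if self.kind == "loguniform" and self.low <= 0:
                raise ValueError(f"dimension '{self.name}': log bounds must be > 0")
        elif self.kind == "choice":
            if not self.choices:
                raise ValueError(f"dimension '{self.name}': empty choice set")
        else:
            raise ValueError(f"dimension '{self.name}': unknown kind '{self.kind}'")

    def sample_prior(self, rng: np.random.Generator):
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        if self.kind == "loguniform":
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        if self.kind == "int":
            return int(rng.integers(int(self.low), int(self.high) + 1))
        return self.choices[rng.integers(len(self.choices))]

    def contains(self, value) -> bool:
        if self.kind == "choice":
            return value in self.choices
        if self.kind == "int":
            return float(value) == int(value) and self.low <= value <= self.high
        return self.low <= value <= self.high


@dataclass
class SearchSpace:
    """Ordered collection of dimensions with tree-structured conditions."""

    dimensions: list[Dimension]

    def __post_init__(self) -> None:
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dimension names")
        self._by_name = {d.name: d for d in self.dimensions}

    def __getitem__(self, name: str) -> Dimension:
        return self._by_name[name]

    def is_active(self, dim: Dimension, config: dict) -> bool:
        if dim.condition is None:
            return True
        parent, value = dim.condition
        return config.get(parent) == value

    def sample_prior(self, rng: np.random.Generator) -> dict:
        config: dict = {}
        for dim in self.dimensions:  # parents must precede children
            if self.is_active(dim, config):
                config[dim.name] = dim.sample_prior(rng)
        return config

    def validate(self, config: dict) -> None:
        for dim in self.dimensions:
            if self.is_active(dim, config):
                if dim.name not in config:
                    raise ValueError(f"missing active dimension '{dim.name}'")
                if not dim.contains(config[dim.name]):
                    raise ValueError(
                        f"value {config[dim.name]!r} outside domain of '{dim.name}'"
                    )
            elif dim.name in config:
                raise ValueError(f"inactive dimension '{dim.name}' present")


@dataclass
class Trial:
    config: dict
    loss: float
    status: str = "ok"  # "ok" | "failed"
    timestamp: float = 0.0


@dataclass
class TrialHistory:
    """Observed (configuration, loss) pairs plus the good/bad split rule."""

    trials: list[Trial] = field(default_factory=list)
    gamma: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")

    def __len__(self) -> int:
        return len(self.trials)

    def append(self, trial: Trial) -> None:
        self.trials.append(trial)

    @property
    def threshold(self) -> float:
        """c*: the gamma-quantile of observed losses."""
        losses = np.array([t.loss for t in self.trials])
        return float(np.quantile(losses, self.gamma))

    def split(self) -> tuple[list[Trial], list[Trial]]:
        """(good, bad) by loss order; good has max(1, ceil(gamma*n)) members.

        Using the sorted order (rather than a strict c* cut) keeps the good
        set nonempty even when all losses are tied.
        """
        n_good = max(1, math.ceil(self.gamma * len(self.trials)))
        order = sorted(range(len(self.trials)), key=lambda i: self.trials[i].loss)
        good_idx = set(order[:n_good])
        good = [t for i, t in enumerate(self.trials) if i in good_idx]
        bad = [t for i, t in enumerate(self.trials) if i not in good_idx]
        return good, bad

    def best(self) -> Trial:
        return min(self.trials, key=lambda t: t.loss)

    def save_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.trials:
                fh.write(
                    json.dumps(
                        {
                            "config": t.config,
                            "loss": t.loss,
                            "status": t.status,
                            "timestamp": t.timestamp,
                        }
                    )
                    + "\n"
                )

    @classmethod
    def load_jsonl(cls, path: str | Path, gamma: float = 0.25) -> "TrialHistory":
        hist = cls(gamma=gamma)
        for line in Path(path).read_text().splitlines():
            if line.strip():
                obj = json.loads(line)
                hist.append(
                    Trial(
                        config=obj["config"],
                        loss=obj["loss"],
                        status=obj.get("status", "ok"),
                        timestamp=obj.get("timestamp", 0.0),
                    )
                )
        return hist


# ---------------------------------------------------------------------------
# per-dimension density estimates


class _ContinuousParzen:
    """Mixture of truncated Gaussians at observations, plus a prior component.

    Bandwidths follow neighbor spacing within the (log-scaled, for
    loguniform dimensions) domain, clipped to keep the kernels neither
    degenerate nor wider than the domain.
    """

    def __init__(self, dim: Dimension, observations: Sequence[float]):
        self.dim = dim
        self.log = dim.kind == "loguniform"
        self.lo = math.log(dim.low) if self.log else float(dim.low)
        self.hi = math.log(dim.high) if self.log else float(dim.high)
        obs = np.array([math.log(v) if self.log else float(v) for v in observations])
        span = self.hi - self.lo
        # prior pseudo-observation at the domain midpoint, full-domain width
        self.mus = np.concatenate([obs, [(self.lo + self.hi) / 2.0]])
        sigmas = np.empty_like(self.mus)
        if len(obs) > 0:
            order = np.argsort(obs)
            sorted_obs = obs[order]
            gaps = np.empty(len(obs))
            for r, i in enumerate(order):
                left = sorted_obs[r] - sorted_obs[r - 1] if r > 0 else span
                right = sorted_obs[r + 1] - sorted_obs[r] if r < len(obs) - 1 else span
                gaps[i] = max(left, right)
            # floor keeps kernels from collapsing onto a tight cluster, which
            # would stall progress at the cluster edge
            sigmas[: len(obs)] = np.clip(gaps, span / 20.0, span)
        sigmas[-1] = span
        self.sigmas = sigmas

    def sample(self, rng: np.random.Generator) -> float:
        i = rng.integers(len(self.mus))
        while True:  # rejection inside the truncated support
            x = rng.normal(self.mus[i], self.sigmas[i])
            if self.lo <= x <= self.hi:
                break
        value = math.exp(x) if self.log else x
        if self.dim.kind == "int":
            value = int(round(value))
            value = int(np.clip(value, self.dim.low, self.dim.high))
        return value

    def logpdf(self, value) -> float:
        x = math.log(value) if self.log else float(value)
        # normalized truncated-Gaussian mixture, equal component weights
        z = (x - self.mus) / self.sigmas
        phi = np.exp(-0.5 * z**2) / (np.sqrt(2 * np.pi) * self.sigmas)
        norm = ndtr((self.hi - self.mus) / self.sigmas) - ndtr(
            (self.lo - self.mus) / self.sigmas
        )
        dens = float(np.mean(phi / np.maximum(norm, 1e-12)))
        return math.log(max(dens, 1e-300))


class _CategoricalParzen:
    """Laplace-smoothed observation counts over the choice set."""

    def __init__(self, dim: Dimension, observations: Sequence):
        self.dim = dim
        counts = np.ones(len(dim.choices))  # +1 smoothing = prior
        index = {c: i for i, c in enumerate(dim.choices)}
        for v in observations:
            counts[index[v]] += 1.0
        self.probs = counts / counts.sum()
        self._index = index

    def sample(self, rng: np.random.Generator):
        return self.dim.choices[rng.choice(len(self.probs), p=self.probs)]

    def logpdf(self, value) -> float:
        return math.log(self.probs[self._index[value]])


def _make_estimator(dim: Dimension, observations: Sequence):
    if dim.kind == "choice":
        return _CategoricalParzen(dim, observations)
    return _ContinuousParzen(dim, observations)


def tpe_suggest(
    history: TrialHistory,
    space: SearchSpace,
    n_candidates: int = 24,
    rng_seed: int | np.random.Generator = 0,
    n_startup: int = 10,
) -> dict:
    """Propose the next configuration.

    Draws from the prior during startup; afterwards builds l (good trials)
    and g (bad trials) per dimension, draws ``n_candidates`` configurations
    from l and returns the one maximizing l/g.  Conditional dimensions use
    only trials in which they were active.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    ok_trials = [t for t in history.trials if t.status == "ok"]
    if len(ok_trials) < n_startup:
        return space.sample_prior(rng)

    good, bad = TrialHistory(trials=ok_trials, gamma=history.gamma).split()
    l_est: dict[str, Any] = {}
    g_est: dict[str, Any] = {}
    for dim in space.dimensions:
        l_obs = [t.config[dim.name] for t in good if dim.name in t.config]
        g_obs = [t.config[dim.name] for t in bad if dim.name in t.config]
        l_est[dim.name] = _make_estimator(dim, l_obs)
        g_est[dim.name] = _make_estimator(dim, g_obs)

    best_config, best_score = None, -math.inf
    for _ in range(n_candidates):
        config: dict = {}
        score = 0.0
        for dim in space.dimensions:
            if not space.is_active(dim, config):
                continue
            value = l_est[dim.name].sample(rng)
            config[dim.name] = value
            score += l_est[dim.name].logpdf(value) - g_est[dim.name].logpdf(value)
        if score > best_score:
            best_config, best_score = config, score
    return best_config


def optimize(
    objective: Callable[[dict], float],
    space: SearchSpace,
    n_trials: int = 100,
    seed: int = 0,
    gamma: float = 0.25,
    n_startup: int = 10,
    n_candidates: int = 24,
    log_path: str | Path | None = None,
) -> tuple[dict, float, TrialHistory]:
    """Sequential TPE minimization of ``objective`` over ``space``.

    Objective exceptions are recorded as failed trials at the worst
    observed loss (1.0 before any success) and optimization continues.
    Returns (best configuration, best loss, full history); identical seed
    plus a deterministic objective reproduce the history exactly.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    history = TrialHistory(gamma=gamma)
    for _ in range(n_trials):
        config = tpe_suggest(
            history, space, n_candidates=n_candidates, rng_seed=rng, n_startup=n_startup
        )
        space.validate(config)
        try:
            loss = float(objective(config))
            status = "ok"
        except Exception:
            ok_losses = [t.loss for t in history.trials if t.status == "ok"]
            loss = max(ok_losses) if ok_losses else 1.0
            status = "failed"
        history.append(
            Trial(config=config, loss=loss, status=status, timestamp=time.time())
        )
        if log_path is not None:
            history.save_jsonl(log_path)
    best = min(
        (t for t in history.trials if t.status == "ok"),
        key=lambda t: t.loss,
        default=history.trials[-1],
    )
    return best.config, best.loss, history


def default_search_space() -> SearchSpace:
    """The network hyper-parameter space used for tuning.

    layers {2,3}; hidden_1 100-800; hidden_2 50-700; hidden_3 25-600
    (only when layers=3); 7 activations; 7 optimizers; learning_rate
    0.001-0.09 (log scale); 7 initializers; dropout 0.1-0.6; epochs
    10-100 step 10; batch_size {40,50,60,70,80}.
    """
    return SearchSpace(
        dimensions=[
            Dimension("layers", "choice", choices=(2, 3)),
            Dimension("hidden_1", "int", low=100, high=800),
            Dimension("hidden_2", "int", low=50, high=700),
            Dimension("hidden_3", "int", low=25, high=600, condition=("layers", 3)),
            Dimension(
                "activation",
                "choice",
                choices=(
                    "elu",
                    "selu",
                    "softplus",
                    "softsign",
                    "relu",
                    "tanh",
                    "hard_sigmoid",
                ),
            ),
            Dimension(
                "optimizer",
                "choice",
                choices=(
                    "RMSprop",
                    "Adam",
                    "Adamax",
                    "SGD",
                    "Nadam",
                    "Adadelta",
                    "Adagrad",
                ),
            ),
            Dimension("learning_rate", "loguniform", low=0.001, high=0.09),
            Dimension(
                "kernel_initializer",
                "choice",
                choices=(
                    "uniform",
                    "normal",
                    "lecun_uniform",
                    "glorot_uniform",
                    "glorot_normal",
                    "he_normal",
                    "he_uniform",
                ),
            ),
            Dimension("dropout", "uniform", low=0.1, high=0.6),
            Dimension("epochs", "choice", choices=tuple(range(10, 101, 10))),
            Dimension("batch_size", "choice", choices=(40, 50, 60, 70, 80)),
        ]
    )
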