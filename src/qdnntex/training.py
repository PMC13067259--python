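"""Parameter optimization for the quantum-classical classifier.

The primary optimizer is simulated annealing over the flattened
``(W, V)`` parameter vector, minimizing the mean binary cross-entropy of
the forward pass (the network is non-differentiable only in the sense
that no analytic gradient is implemented; an optional central-finite-
difference gradient-descent mode covers the conventional
learning-rate/epoch/batch training style with the package defaults
lr=0.01, 200 epochs, batch size 32).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annealing import AnnealSchedule, AnnealTrace, anneal
from .qdnn import QDNNArchitecture, QDNNParams, forward_batch, mean_loss


@dataclass
class TrainConfig:
    """Optimizer settings for both training modes."""

    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    sigma_param: float = 0.1
    lr: float = 0.01
    epochs: int = 200
    batch_size: int = 32
    mode: str = "sa"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_param <= 0:
            raise ValueError("sigma_param must be > 0")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.mode not in ("sa", "gd", "sa+gd"):
            raise ValueError("mode must be 'sa', 'gd' or 'sa+gd'")


def qdnn_energy(params: QDNNParams, X: np.ndarray, y: np.ndarray,
                arch: QDNNArchitecture) -> float:
    """Mean binary cross-entropy of the forward pass under ``params``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty data")
    return mean_loss(y, forward_batch(X, arch, params))


def init_params(arch: QDNNArchitecture, rng: np.random.Generator) -> QDNNParams:
    """Small random initialization, uniform(-0.1, 0.1): keeps the
    entangling layer near the identity so early proposals explore
    gently."""
    W = rng.uniform(-0.1, 0.1, size=(arch.M, arch.N))
    V = rng.uniform(-0.1, 0.1, size=arch.M)
    return QDNNParams(W=W, V=V)


def train_sa(arch: QDNNArchitecture, X: np.ndarray, y: np.ndarray,
             config: TrainConfig | None = None):
    """Simulated-annealing training; returns ``(best_params, trace)``.

    Proposals add i.i.d. Gaussian noise (std ``sigma_param``) to every
    entry of the flattened parameter vector.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    x0 = init_params(arch, rng).flatten()

    def energy(vec):
        return qdnn_energy(QDNNParams.from_flat(vec, arch), X, y, arch)

    def perturb(vec, r):
        return vec + r.normal(0.0, cfg.sigma_param, size=vec.shape)

    best_vec, trace = anneal(energy, perturb, x0, cfg.schedule, rng)
    return QDNNParams.from_flat(best_vec, arch), trace


def train_gd(arch: QDNNArchitecture, X: np.ndarray, y: np.ndarray,
             config: TrainConfig | None = None,
             initial: QDNNParams | None = None) -> QDNNParams:
    """Mini-batch gradient descent with central finite differences.

    Per epoch the samples are shuffled (seeded) and iterated in batches;
    the gradient of the batch loss is estimated coordinate-wise with a
    central difference of step 1e-4 and the parameters updated by
    ``theta -= lr * grad``.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = (initial or init_params(arch, rng)).flatten()
    h = 1e-4
    n = X.shape[0]

    def batch_energy(vec, bX, by):
        return mean_loss(by, forward_batch(bX, arch, QDNNParams.from_flat(vec, arch)))

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            bX, by = X[idx], y[idx]
            grad = np.empty_like(theta)
            for k in range(theta.size):
                tp = theta.copy(); tp[k] += h
                tm = theta.copy(); tm[k] -= h
                grad[k] = (batch_energy(tp, bX, by) - batch_energy(tm, bX, by)) / (2 * h)
            theta = theta - cfg.lr * grad
    return QDNNParams.from_flat(theta, arch)


def train(arch: QDNNArchitecture, X: np.ndarray, y: np.ndarray,
          config: TrainConfig | None = None):
    """Dispatch on ``config.mode``: 'sa' (default), 'gd', or 'sa+gd'
    (annealing followed by gradient refinement).  Returns
    ``(params, trace_or_None)``."""
    cfg = config or TrainConfig()
    if cfg.mode == "sa":
        return train_sa(arch, X, y, cfg)
    if cfg.mode == "gd":
        return train_gd(arch, X, y, cfg), None
    params, trace = train_sa(arch, X, y, cfg)
    return train_gd(arch, X, y, cfg, initial=params), trace
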