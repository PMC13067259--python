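"""Feature-specific simulated annealing (FSSA).

Rather than discarding features, FSSA assigns every feature a continuous
weight in ``[0, 1]`` and anneals the weight vector to maximize

    obj(w) = a * accuracy(F_w) - b * redundancy(F_w)

where ``F_w`` is the column-wise weighted feature matrix, accuracy is a
fast internal estimate of class separability on a held-out split, and
redundancy is the mean absolute pairwise Pearson correlation between
weighted columns.  Down-weighting a redundant column lowers its
correlation contribution only through the accuracy trade-off (a constant
scaling leaves Pearson correlation unchanged, but driving a weight to
zero makes a column constant, which contributes zero redundancy).

The accuracy evaluator is pluggable.  The default is a nearest-class-
centroid classifier on a seeded stratified 75/25 split: a few
milliseconds per call, which is what makes 500 annealing iterations
practical.  A full classifier (e.g. the quantum network in this
package) can be substituted for a slower, higher-fidelity objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split

from .annealing import AnnealSchedule, AnnealTrace, anneal


@dataclass
class FSSAConfig:
    """Objective and search settings.

    ``a`` and ``b`` balance accuracy against redundancy; ``sigma_perturb``
    is the standard deviation of the Gaussian weight perturbation
    (defaults explore ~5% of the unit weight range per step).
    """

    a: float = 1.0
    b: float = 0.5
    sigma_perturb: float = 0.05
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    val_fraction: float = 0.25
    seed: int = 0
    evaluator: Callable | None = None

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("a and b must be >= 0")
        if self.sigma_perturb <= 0:
            raise ValueError("sigma_perturb must be > 0")
        if not (0 < self.val_fraction <= 0.5):
            raise ValueError("val_fraction must lie in (0, 0.5]")


def apply_weights(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Column-wise product ``X[:, k] * w[k]``."""
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    if X.ndim != 2 or w.ndim != 1 or X.shape[1] != w.shape[0]:
        raise ValueError("weight length must match the feature count")
    return X * w[np.newaxis, :]


def redundancy(Xw: np.ndarray) -> float:
    """Mean absolute Pearson correlation over unordered column pairs.

    Pairs involving a constant column contribute 0; a single-column
    matrix returns 0 (no pairs).  The value lies in ``[0, 1]``.
    """
    Xw = np.asarray(Xw, dtype=float)
    if Xw.ndim != 2 or Xw.shape[1] < 1:
        raise ValueError("expected a 2-D matrix with >= 1 feature")
    n_feat = Xw.shape[1]
    if n_feat == 1:
        return 0.0
    std = Xw.std(axis=0)
    ok = std > 0
    total = 0.0
    if ok.sum() >= 2:
        sub = Xw[:, ok]
        with np.errstate(invalid="ignore"):
            corr = np.abs(np.corrcoef(sub, rowvar=False))
        iu = np.triu_indices(corr.shape[0], k=1)
        total = np.nan_to_num(corr[iu]).sum()
    n_pairs = n_feat * (n_feat - 1) // 2
    return float(total / n_pairs)


def reference_accuracy(Xw: np.ndarray, y: np.ndarray,
                       val_fraction: float = 0.25, seed: int = 0) -> float:
    """Hold-out accuracy of a nearest-class-centroid classifier.

    Deterministically splits the samples (stratified by label, seeded),
    fits per-class centroids on the training part of the weighted
    features, and scores the validation part by nearest centroid
    (Euclidean; ties resolve to the lowest class index via the fixed
    argmin order).
    """
    Xw = np.asarray(Xw, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 samples")
    X_tr, X_va, y_tr, y_va = train_test_split(
        Xw, y, test_size=val_fraction, stratify=y, random_state=seed)
    train_classes = np.unique(y_tr)
    centroids = np.vstack([X_tr[y_tr == c].mean(axis=0) for c in train_classes])
    # argmin takes the first minimum, so exact ties resolve to the lowest
    # class index (this also covers the all-zero-weights degenerate case)
    pred = train_classes[np.argmin(cdist(X_va, centroids), axis=1)]
    return float((pred == y_va).mean())


def objective(w: np.ndarray, X: np.ndarray, y: np.ndarray,
              config: FSSAConfig | None = None) -> float:
    """``a * accuracy - b * redundancy`` at weights ``w``."""
    cfg = config or FSSAConfig()
    Xw = apply_weights(X, w)
    evaluate = cfg.evaluator or reference_accuracy
    acc = evaluate(Xw, y, cfg.val_fraction, cfg.seed) if cfg.a > 0 else 0.0
    red = redundancy(Xw) if cfg.b > 0 else 0.0
    return cfg.a * acc - cfg.b * red


def perturb_weights(w: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise N(0, sigma^2) to every weight, then
    clip to ``[0, 1]``."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    w = np.asarray(w, dtype=float)
    return np.clip(w + rng.normal(0.0, sigma, size=w.shape), 0.0, 1.0)


def run_fssa(X: np.ndarray, y: np.ndarray, config: FSSAConfig | None = None):
    """Anneal feature weights on ``(X, y)``.

    Weights start uniform at random in ``[0, 1]^n`` (seeded) and the
    engine minimizes ``-objective``.  Returns ``(best_weights, trace)``;
    the trace records energies, i.e. negated objective values.
    """
    cfg = config or FSSAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    rng = np.random.default_rng(cfg.seed)
    w0 = rng.uniform(0.0, 1.0, size=X.shape[1])

    def energy(w):
        return -objective(w, X, y, cfg)

    def perturb(w, r):
        return perturb_weights(w, cfg.sigma_perturb, r)

    best, trace = anneal(energy, perturb, w0, cfg.schedule, rng)
    return np.asarray(best), trace


def weights_to_csv(weights: np.ndarray, feature_names, path) -> None:
    pd.DataFrame({"feature_name": list(feature_names),
                  "weight": np.asarray(weights, dtype=float)}).to_csv(path, index=False)


def weights_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


class FSSAWeighter:
    """scikit-learn style transformer learning per-feature weights.

    ``fit`` anneals the weights on the training data; ``transform``
    scales columns by the learned weights.  Fitted attributes:
    ``weights_`` (the best weight vector), ``trace_`` (the annealing
    trace), ``objective_`` (best objective value reached).
    """

    def __init__(self, a: float = 1.0, b: float = 0.5, sigma_perturb: float = 0.05,
                 T0: float = 1.0, gamma: float = 0.95, max_iter: int = 500,
                 T_min: float = 1e-6, val_fraction: float = 0.25,
                 random_state: int = 0, evaluator: Callable | None = None):
        self.a = a
        self.b = b
        self.sigma_perturb = sigma_perturb
        self.T0 = T0
        self.gamma = gamma
        self.max_iter = max_iter
        self.T_min = T_min
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.evaluator = evaluator

    _param_names = ("a", "b", "sigma_perturb", "T0", "gamma", "max_iter",
                    "T_min", "val_fraction", "random_state", "evaluator")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> FSSAConfig:
        return FSSAConfig(
            a=self.a, b=self.b, sigma_perturb=self.sigma_perturb,
            schedule=AnnealSchedule(T0=self.T0, gamma=self.gamma,
                                    max_iter=self.max_iter, T_min=self.T_min),
            val_fraction=self.val_fraction, seed=self.random_state,
            evaluator=self.evaluator)

    def fit(self, X, y):
        weights, trace = run_fssa(np.asarray(X, dtype=float), np.asarray(y), self._config())
        self.weights_ = weights
        self.trace_ = trace
        self.objective_ = -trace.final_best_energy
        self.n_features_in_ = weights.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        return apply_weights(np.asarray(X, dtype=float), self.weights_)

    def fit_transform(self, X, y) -> np.ndarray:
        return self.fit(X, y).transform(X)
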