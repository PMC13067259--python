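"""scikit-learn style estimator wrapping the quantum-classical network.

``QDNNClassifier`` handles the classical plumbing around the circuit:
per-column min-max scaling into the ``[0, 1]`` range amplitude encoding
requires, selection of the top-``N`` feature columns when more features
than input qubits are available (ranked by externally supplied
relevance weights, e.g. annealed feature weights; ties and the
unweighted case fall back to column order), and one-vs-rest binary
heads with argmax prediction.

One head is trained per class even in the two-class case.  The circuit
readout ``sigmoid(sum_j V_j tanh(a_j))`` pins ``y_hat = 0.5`` whenever
every feature equals 1 (all hidden expectations vanish there), so a
fixed 0.5 threshold on a single head is not a reliable decision rule;
comparing per-class heads is, and it keeps binary and multiclass
prediction on the same code path.
"""

from __future__ import annotations

import json

import numpy as np

from .annealing import AnnealSchedule
from .qdnn import QDNNArchitecture, QDNNParams, forward_batch
from .training import TrainConfig, train


class QDNNClassifier:
    """Hybrid quantum-classical classifier with annealing-based training.

    Parameters
    ----------
    n_input_qubits, n_hidden_qubits, n_output_qubits : int
        Register layout (one feature per input qubit).
    mode : {"sa", "gd", "sa+gd"}
        Training mode; simulated annealing is the default.
    T0, gamma, max_iter, T_min : float
        Annealing schedule (defaults 1.0, 0.95, 500, 1e-6).
    sigma_param : float
        Gaussian proposal std for annealing, in radians.
    lr, epochs, batch_size : gradient-mode settings (0.01, 200, 32).
    random_state : int
        Seed for initialization and proposals.

    Fitted attributes: ``classes_``, ``selected_features_`` (column
    indices encoded on the input qubits), ``scale_min_``/``scale_max_``,
    ``heads_`` (per-class :class:`QDNNParams`), ``traces_``.
    """

    def __init__(self, n_input_qubits: int = 4, n_hidden_qubits: int = 2,
                 n_output_qubits: int = 1, mode: str = "sa",
                 T0: float = 1.0, gamma: float = 0.95, max_iter: int = 500,
                 T_min: float = 1e-6, sigma_param: float = 0.1,
                 lr: float = 0.01, epochs: int = 200, batch_size: int = 32,
                 random_state: int = 0):
        self.n_input_qubits = n_input_qubits
        self.n_hidden_qubits = n_hidden_qubits
        self.n_output_qubits = n_output_qubits
        self.mode = mode
        self.T0 = T0
        self.gamma = gamma
        self.max_iter = max_iter
        self.T_min = T_min
        self.sigma_param = sigma_param
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    _param_names = ("n_input_qubits", "n_hidden_qubits", "n_output_qubits", "mode",
                    "T0", "gamma", "max_iter", "T_min", "sigma_param",
                    "lr", "epochs", "batch_size", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def _architecture(self) -> QDNNArchitecture:
        return QDNNArchitecture(N=self.n_input_qubits, M=self.n_hidden_qubits,
                                K=self.n_output_qubits)

    def _train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            schedule=AnnealSchedule(T0=self.T0, gamma=self.gamma,
                                    max_iter=self.max_iter, T_min=self.T_min),
            sigma_param=self.sigma_param, lr=self.lr, epochs=self.epochs,
            batch_size=self.batch_size, mode=self.mode, seed=seed)

    def _select(self, n_features: int, feature_weights) -> np.ndarray:
        N = self.n_input_qubits
        if n_features < N:
            raise ValueError(f"need at least {N} feature columns, got {n_features}")
        if feature_weights is None:
            feature_weights = np.ones(n_features)
        w = np.asarray(feature_weights, dtype=float)
        if w.shape != (n_features,):
            raise ValueError("feature_weights length must match the feature count")
        # stable sort keeps column order among equal weights
        return np.sort(np.argsort(-w, kind="stable")[:N])

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = self.scale_max_ - self.scale_min_
        out = np.empty_like(X)
        ok = span > 0
        out[:, ok] = (X[:, ok] - self.scale_min_[ok]) / span[ok]
        out[:, ~ok] = 0.5  # constant training column: neutral superposition
        return np.clip(out, 0.0, 1.0)

    def fit(self, X, y, feature_weights=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 classes")
        arch = self._architecture()

        self.selected_features_ = self._select(X.shape[1], feature_weights)
        Xs = X[:, self.selected_features_]
        self.scale_min_ = Xs.min(axis=0)
        self.scale_max_ = Xs.max(axis=0)
        X01 = self._scale(Xs)

        self.heads_ = []
        self.traces_ = []
        for c_idx, c in enumerate(self.classes_):
            yb = (y == c).astype(float)
            seed = (int(self.random_state) + 9973 * c_idx) % (2 ** 31)
            params, trace = train(arch, X01, yb, self._train_config(seed))
            self.heads_.append(params)
            self.traces_.append(trace)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-class head probabilities, one column per class."""
        X = np.asarray(X, dtype=float)
        arch = self._architecture()
        X01 = self._scale(X[:, self.selected_features_])
        return np.column_stack([forward_batch(X01, arch, h) for h in self.heads_])

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return scores / scores.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        # argmax takes the first maximum: ties resolve to the lowest class
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "architecture": {"N": self.n_input_qubits, "M": self.n_hidden_qubits,
                             "K": self.n_output_qubits},
            "classes": [int(c) if np.issubdtype(type(c), np.integer) else c
                        for c in self.classes_.tolist()],
            "selected_features": self.selected_features_.tolist(),
            "scale_min": self.scale_min_.tolist(),
            "scale_max": self.scale_max_.tolist(),
            "heads": [{"W": h.W.tolist(), "V": h.V.tolist()} for h in self.heads_],
            "params": {k: getattr(self, k) for k in self._param_names},
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, payload: dict) -> "QDNNClassifier":
        est = cls(**payload["params"])
        est.classes_ = np.asarray(payload["classes"])
        est.selected_features_ = np.asarray(payload["selected_features"], dtype=int)
        est.scale_min_ = np.asarray(payload["scale_min"], dtype=float)
        est.scale_max_ = np.asarray(payload["scale_max"], dtype=float)
        est.heads_ = [QDNNParams(W=np.asarray(h["W"]), V=np.asarray(h["V"]))
                      for h in payload["heads"]]
        est.traces_ = []
        return est

    @classmethod
    def load_json(cls, path) -> "QDNNClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
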