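"""Hybrid quantum-classical classifier on an exact state-vector simulator.

Architecture
------------
The register holds ``N`` input qubits, ``M`` hidden qubits and ``K``
output qubits (``K`` is kept for the qubit count but carries no gates in
binary mode; the classical readout plays the output layer's role):

1. each min-max-scaled feature ``x in [0, 1]`` is amplitude-encoded on
   one input qubit as ``sqrt(x)|0> + sqrt(1-x)|1>``;
2. the hidden register starts in the uniform superposition (Hadamard on
   every hidden qubit);
3. an entangling layer applies a controlled-R_y(W[j, i]) for every
   input qubit *i* (control, active on |1>) and hidden qubit *j*
   (target), in fixed (i ascending, then j ascending) order — the
   unitary realization of a dense input-to-hidden weight matrix;
4. each hidden qubit is read out as its exact Z-expectation
   ``a_j = P(0) - P(1)`` (no sampling noise);
5. classically, ``y_hat = sigmoid( sum_j V_j * tanh(a_j) )``.

Everything is deterministic; multiclass prediction uses one-vs-rest
binary heads and argmax.

Qubit order is most-significant-first: qubit 0 is the highest bit of
the basis-state index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_QUBITS = 14  # state-vector tractability guard

_H = np.array([[1.0, 1.0], [1.0, -1.0]]) / np.sqrt(2.0)


@dataclass
class QDNNArchitecture:
    """Qubit layout: N input, M hidden, K output qubits."""

    N: int
    M: int
    K: int = 1

    def __post_init__(self) -> None:
        if self.N < 1 or self.M < 1 or self.K < 1:
            raise ValueError("N, M and K must all be >= 1")
        if self.N + self.M > MAX_QUBITS:
            raise ValueError(f"N + M must be <= {MAX_QUBITS} for state-vector simulation")

    @property
    def total_qubits(self) -> int:
        return self.N + self.M + self.K


@dataclass
class QDNNParams:
    """Trainable parameters: W (M x N controlled-rotation angles, radians)
    and V (M classical readout weights)."""

    W: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.W.ndim != 2 or self.V.ndim != 1 or self.W.shape[0] != self.V.shape[0]:
            raise ValueError("W must be (M, N) and V must be (M,)")
        if not (np.isfinite(self.W).all() and np.isfinite(self.V).all()):
            raise ValueError("parameters must be finite")

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.W.ravel(), self.V])

    @classmethod
    def from_flat(cls, vec: np.ndarray, arch: QDNNArchitecture) -> "QDNNParams":
        vec = np.asarray(vec, dtype=float)
        n_w = arch.M * arch.N
        return cls(W=vec[:n_w].reshape(arch.M, arch.N), V=vec[n_w:n_w + arch.M])


def _check_state(state: np.ndarray) -> np.ndarray:
    amp = np.asarray(state, dtype=complex)
    n = int(np.log2(amp.size))
    if 2 ** n != amp.size:
        raise ValueError("state length must be a power of 2")
    return amp


def uniform_superposition(n_qubits: int) -> np.ndarray:
    """All 2^n amplitudes equal to 1/sqrt(2^n) (H on every |0> qubit)."""
    if not (1 <= n_qubits <= MAX_QUBITS):
        raise ValueError(f"n_qubits must lie in [1, {MAX_QUBITS}]")
    dim = 2 ** n_qubits
    return np.full(dim, 1.0 / np.sqrt(dim), dtype=complex)


def hadamard_layer(state: np.ndarray, qubits) -> np.ndarray:
    """Apply the 2x2 Hadamard to each listed qubit of the register."""
    amp = _check_state(state)
    n = int(np.log2(amp.size))
    qubits = list(qubits)
    if len(set(qubits)) != len(qubits):
        raise ValueError("duplicate qubit index")
    if any(q < 0 or q >= n for q in qubits):
        raise ValueError("qubit index out of range")
    tensor = amp.reshape((2,) * n)
    for q in qubits:
        tensor = np.moveaxis(np.tensordot(_H, tensor, axes=([1], [q])), 0, q)
    return tensor.reshape(-1)


def amplitude_encode(x: float) -> np.ndarray:
    """One-qubit amplitude encoding: sqrt(x)|0> + sqrt(1-x)|1>."""
    if not (0.0 <= x <= 1.0):
        raise ValueError("feature value must lie in [0, 1]; scale features first")
    return np.array([np.sqrt(x), np.sqrt(1.0 - x)], dtype=complex)


def encode_sample(features) -> np.ndarray:
    """Tensor product of per-feature encoded qubits (first feature most
    significant)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 1 or features.size < 1:
        raise ValueError("features must be a non-empty 1-D sequence")
    state = np.ones(1, dtype=complex)
    for x in features:
        state = np.kron(state, amplitude_encode(float(x)))
    return state


def _ry(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]], dtype=complex)


def controlled_ry(state: np.ndarray, control: int, target: int, theta: float) -> np.ndarray:
    """Apply R_y(theta) on ``target`` conditioned on ``control`` = |1>."""
    amp = _check_state(state)
    n = int(np.log2(amp.size))
    if control == target or not (0 <= control < n and 0 <= target < n):
        raise ValueError("invalid control/target qubit indices")
    tensor = amp.reshape((2,) * n).copy()
    # slice with control fixed to 1, rotate along the target axis
    idx = [slice(None)] * n
    idx[control] = 1
    sub = tensor[tuple(idx)]
    t_axis = target - (1 if control < target else 0)
    sub0 = np.take(sub, 0, axis=t_axis)
    sub1 = np.take(sub, 1, axis=t_axis)
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    new0 = c * sub0 - s * sub1
    new1 = s * sub0 + c * sub1
    sub = np.stack([new0, new1], axis=t_axis)
    tensor[tuple(idx)] = sub
    return tensor.reshape(-1)


def apply_entangling_layer(state: np.ndarray, W: np.ndarray,
                           n_input: int, n_hidden: int) -> np.ndarray:
    """Dense input-to-hidden coupling via controlled-R_y gates.

    For every input qubit *i* and hidden qubit *j*, applies a
    controlled-R_y(W[j, i]) with control *i* and target ``n_input + j``,
    in (i ascending, then j ascending) order.  ``W = 0`` is the
    identity.
    """
    W = np.asarray(W, dtype=float)
    amp = _check_state(state)
    n = int(np.log2(amp.size))
    if W.shape != (n_hidden, n_input):
        raise ValueError("W must have shape (n_hidden, n_input)")
    if n != n_input + n_hidden:
        raise ValueError("state register must hold exactly the input+hidden qubits")
    for i in range(n_input):
        for j in range(n_hidden):
            if W[j, i] != 0.0:
                amp = controlled_ry(amp, control=i, target=n_input + j, theta=W[j, i])
    return amp


def measure_expectations(state: np.ndarray, qubits) -> np.ndarray:
    """Exact Z-expectation ``P(0) - P(1)`` of each listed qubit."""
    amp = _check_state(state)
    n = int(np.log2(amp.size))
    probs = np.abs(amp) ** 2
    tensor = probs.reshape((2,) * n)
    out = []
    for q in qubits:
        if not (0 <= q < n):
            raise ValueError("qubit index out of range")
        axes = tuple(a for a in range(n) if a != q)
        marg = tensor.sum(axis=axes)
        out.append(marg[0] - marg[1])
    return np.asarray(out, dtype=float)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def forward(features, arch: QDNNArchitecture, params: QDNNParams) -> float:
    """Deterministic forward pass producing ``y_hat in (0, 1)``.

    encode -> Hadamard-initialized hidden register -> entangling layer
    -> Z-expectations -> ``sigmoid(sum_j V_j tanh(a_j))``.
    """
    features = np.asarray(features, dtype=float)
    if features.shape != (arch.N,):
        raise ValueError(f"expected {arch.N} features")
    if params.W.shape != (arch.M, arch.N):
        raise ValueError("parameter shapes do not match the architecture")
    state = np.kron(encode_sample(features), uniform_superposition(arch.M))
    state = apply_entangling_layer(state, params.W, arch.N, arch.M)
    a = measure_expectations(state, range(arch.N, arch.N + arch.M))
    o = float(params.V @ np.tanh(a))
    return float(_sigmoid(o))


def forward_batch(X: np.ndarray, arch: QDNNArchitecture, params: QDNNParams) -> np.ndarray:
    """Vectorized forward pass over the rows of ``X`` (each in [0,1]^N).

    Identical to calling :func:`forward` per row; amplitudes are real
    throughout (the circuit uses only H and R_y), so the batch path
    works in float64 for speed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != arch.N:
        raise ValueError(f"X must be (n_samples, {arch.N})")
    if np.any(X < 0) or np.any(X > 1):
        raise ValueError("features must lie in [0, 1]; scale features first")
    B = X.shape[0]
    n = arch.N + arch.M

    # build per-sample product states
    state = np.ones((B, 1))
    for k in range(arch.N):
        q = np.stack([np.sqrt(X[:, k]), np.sqrt(1.0 - X[:, k])], axis=1)
        state = (state[:, :, None] * q[:, None, :]).reshape(B, -1)
    hidden = np.full(2 ** arch.M, 1.0 / np.sqrt(2 ** arch.M))
    state = (state[:, :, None] * hidden[None, None, :]).reshape(B, -1)

    tensor = state.reshape((B,) + (2,) * n)
    for i in range(arch.N):
        for j in range(arch.M):
            theta = params.W[j, i]
            if theta == 0.0:
                continue
            idx = [slice(None)] * (n + 1)
            idx[1 + i] = 1
            sub = tensor[tuple(idx)]
            t_axis = 1 + arch.N + j - (1 if i < arch.N + j else 0)
            sub0 = np.take(sub, 0, axis=t_axis)
            sub1 = np.take(sub, 1, axis=t_axis)
            c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
            stacked = np.stack([c * sub0 - s * sub1, s * sub0 + c * sub1], axis=t_axis)
            tensor[tuple(idx)] = stacked

    probs = tensor.reshape(B, -1) ** 2
    ptensor = probs.reshape((B,) + (2,) * n)
    a = np.empty((B, arch.M))
    for j in range(arch.M):
        axes = tuple(ax for ax in range(1, n + 1) if ax != 1 + arch.N + j)
        marg = ptensor.sum(axis=axes)
        a[:, j] = marg[:, 0] - marg[:, 1]
    o = np.tanh(a) @ params.V
    return _sigmoid(o)


def bce_loss(y: int, y_hat: float, clip: float = 1e-12) -> float:
    """Binary cross-entropy with clipping, natural log."""
    if y not in (0, 1):
        raise ValueError("y must be 0 or 1")
    p = min(max(float(y_hat), clip), 1.0 - clip)
    return float(-(y * np.log(p) + (1 - y) * np.log(1.0 - p)))


def mean_loss(labels, predictions, clip: float = 1e-12) -> float:
    """Arithmetic mean of per-sample binary cross-entropies."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    p = np.clip(predictions, clip, 1.0 - clip)
    return float(np.mean(-(labels * np.log(p) + (1 - labels) * np.log(1.0 - p))))


def predict_multiclass(features, arch: QDNNArchitecture, heads) -> int:
    """One-vs-rest prediction: argmax of the per-head probabilities,
    ties resolved to the lowest class index."""
    heads = list(heads)
    if len(heads) < 2:
        raise ValueError("need >= 2 heads")
    scores = [forward(features, arch, h) for h in heads]
    return int(np.argmax(scores))
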