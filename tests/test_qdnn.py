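import math
from functools import reduce

import numpy as np
import pytest

from qdnntex.qdnn import (QDNNArchitecture, QDNNParams, amplitude_encode,
                          apply_entangling_layer, bce_loss, encode_sample,
                          forward, forward_batch, hadamard_layer, mean_loss,
                          measure_expectations, predict_multiclass,
                          uniform_superposition)

I2 = np.eye(2)
H = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
P0 = np.diag([1.0, 0.0])
P1 = np.diag([0.0, 1.0])
Z = np.diag([1.0, -1.0])


def kron_all(mats):
    return reduce(np.kron, mats)


def op_on(n, q, U):
    """Dense operator applying U on qubit q (most-significant-first)."""
    return kron_all([U if k == q else I2 for k in range(n)])


def cry_dense(n, control, target, theta):
    ry = np.array([[math.cos(theta / 2), -math.sin(theta / 2)],
                   [math.sin(theta / 2), math.cos(theta / 2)]])
    with_p0 = kron_all([P0 if k == control else I2 for k in range(n)])
    with_p1 = kron_all([P1 if k == control else (ry if k == target else I2)
                        for k in range(n)])
    return with_p0 + with_p1


def forward_dense_oracle(features, arch, params):
    """Independent forward pass built from explicit 2^n x 2^n gate
    matrices and dense Z-expectation operators."""
    n = arch.N + arch.M
    psi = np.kron(encode_sample(features),
                  np.full(2 ** arch.M, 1 / np.sqrt(2 ** arch.M), dtype=complex))
    for i in range(arch.N):
        for j in range(arch.M):
            psi = cry_dense(n, i, arch.N + j, params.W[j, i]) @ psi
    a = [np.real(np.conj(psi) @ (op_on(n, arch.N + j, Z) @ psi))
         for j in range(arch.M)]
    o = float(np.asarray(params.V) @ np.tanh(a))
    return 1.0 / (1.0 + math.exp(-o))


class TestStates:
    @pytest.mark.parametrize("n,amp", [(1, 1 / math.sqrt(2)), (2, 0.5),
                                       (3, 1 / math.sqrt(8))])
    def test_uniform_superposition(self, n, amp):
        state = uniform_superposition(n)
        np.testing.assert_allclose(state, np.full(2 ** n, amp))

    def test_qubit_guard(self):
        with pytest.raises(ValueError):
            uniform_superposition(0)
        with pytest.raises(ValueError):
            uniform_superposition(15)

    def test_hadamard_on_basis_states(self):
        np.testing.assert_allclose(hadamard_layer(np.array([1.0, 0.0]), [0]),
                                   [1 / math.sqrt(2), 1 / math.sqrt(2)])
        np.testing.assert_allclose(hadamard_layer(np.array([0.0, 1.0]), [0]),
                                   [1 / math.sqrt(2), -1 / math.sqrt(2)])

    def test_hadamard_is_involution(self, rng):
        state = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        state /= np.linalg.norm(state)
        twice = hadamard_layer(hadamard_layer(state, [0, 2]), [0, 2])
        np.testing.assert_allclose(twice, state, atol=1e-10)

    def test_hadamard_bad_indices(self):
        with pytest.raises(ValueError):
            hadamard_layer(np.ones(4) / 2, [0, 0])
        with pytest.raises(ValueError):
            hadamard_layer(np.ones(4) / 2, [2])

    def test_hadamard_matches_dense_oracle(self, rng):
        state = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        state /= np.linalg.norm(state)
        got = hadamard_layer(state, [1, 3])
        want = op_on(4, 1, H) @ op_on(4, 3, H) @ state
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestEncoding:
    @pytest.mark.parametrize("x,expected", [
        (1.0, [1.0, 0.0]), (0.0, [0.0, 1.0]),
        (0.5, [1 / math.sqrt(2), 1 / math.sqrt(2)])])
    def test_amplitude_encode(self, x, expected):
        np.testing.assert_allclose(amplitude_encode(x), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            amplitude_encode(1.2)

    def test_encode_sample_basis_state(self):
        np.testing.assert_allclose(encode_sample([1.0, 0.0]), [0, 1, 0, 0])

    def test_encode_sample_equal_superposition(self):
        np.testing.assert_allclose(encode_sample([0.5, 0.5]), np.full(4, 0.5))

    def test_encode_sample_tensor_product_arithmetic(self):
        got = encode_sample([0.25, 0.75])
        want = np.sqrt([0.1875, 0.0625, 0.5625, 0.1875])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_unit_norm(self, rng):
        for _ in range(10):
            state = encode_sample(rng.random(4))
            assert np.abs(np.vdot(state, state) - 1) < 1e-10


class TestEntanglingLayer:
    def test_zero_angles_are_identity(self, rng):
        state = rng.standard_normal(8) + 0j
        state /= np.linalg.norm(state)
        out = apply_entangling_layer(state, np.zeros((1, 2)), 2, 1)
        np.testing.assert_allclose(out, state, atol=1e-12)

    def test_pi_rotation_flips_hidden_when_control_set(self):
        # input |1>, hidden |0>; control satisfied -> R_y(pi)|0> = |1>
        state = np.kron([0.0, 1.0], [1.0, 0.0]).astype(complex)
        out = apply_entangling_layer(state, np.array([[math.pi]]), 1, 1)
        want = np.kron([0.0, 1.0], [0.0, 1.0])
        np.testing.assert_allclose(out, want, atol=1e-12)

    def test_matches_dense_gate_oracle(self, rng):
        W = rng.uniform(-math.pi, math.pi, size=(2, 2))
        state = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        state /= np.linalg.norm(state)
        got = apply_entangling_layer(state, W, 2, 2)
        want = state.copy()
        for i in range(2):
            for j in range(2):
                want = cry_dense(4, i, 2 + j, W[j, i]) @ want
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_unitary_preserves_inner_products(self, rng):
        W = rng.uniform(-2, 2, size=(2, 1))
        states = []
        for _ in range(2):
            s = rng.standard_normal(8) + 1j * rng.standard_normal(8)
            states.append(s / np.linalg.norm(s))
        outs = [apply_entangling_layer(s, W, 1, 2) for s in states]
        assert abs(np.vdot(states[0], states[1]) - np.vdot(outs[0], outs[1])) < 1e-10

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            apply_entangling_layer(np.ones(8) / math.sqrt(8), np.zeros((2, 2)), 2, 1)


class TestMeasurement:
    def test_basis_and_superposition_expectations(self):
        assert measure_expectations(np.array([1.0, 0.0]), [0])[0] == pytest.approx(1.0)
        assert measure_expectations(uniform_superposition(1), [0])[0] == pytest.approx(0.0)

    def test_partial_probability(self):
        state = np.array([math.sqrt(0.3), math.sqrt(0.7)])
        assert measure_expectations(state, [0])[0] == pytest.approx(-0.4)


class TestForward:
    def test_zero_readout_gives_half(self, rng):
        arch = QDNNArchitecture(N=2, M=2)
        params = QDNNParams(W=rng.uniform(-1, 1, (2, 2)), V=np.zeros(2))
        assert forward(rng.random(2), arch, params) == pytest.approx(0.5)

    def test_zero_entangler_gives_half(self, rng):
        arch = QDNNArchitecture(N=2, M=2)
        params = QDNNParams(W=np.zeros((2, 2)), V=rng.uniform(-3, 3, 2))
        for _ in range(5):
            assert forward(rng.random(2), arch, params) == pytest.approx(0.5)

    def test_engineered_unit_expectation(self):
        # feature 0 -> input |1>; R_y(-pi/2) maps the uniform hidden
        # qubit exactly onto |0>, so a_1 = 1 and y = sigmoid(2 tanh 1)
        arch = QDNNArchitecture(N=1, M=1)
        params = QDNNParams(W=np.array([[-math.pi / 2]]), V=np.array([2.0]))
        want = 1.0 / (1.0 + math.exp(-2.0 * math.tanh(1.0)))
        assert forward(np.array([0.0]), arch, params) == pytest.approx(want, abs=1e-10)
        assert forward_dense_oracle([0.0], arch, params) == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("N,M", [(1, 1), (2, 1), (1, 2), (2, 2), (3, 1)])
    def test_agrees_with_dense_matrix_oracle(self, N, M, rng):
        arch = QDNNArchitecture(N=N, M=M)
        for _ in range(5):
            params = QDNNParams(W=rng.uniform(-math.pi, math.pi, (M, N)),
                                V=rng.uniform(-2, 2, M))
            x = rng.random(N)
            got = forward(x, arch, params)
            want = forward_dense_oracle(x, arch, params)
            assert got == pytest.approx(want, abs=1e-10)

    def test_batch_matches_single(self, rng):
        arch = QDNNArchitecture(N=3, M=2)
        params = QDNNParams(W=rng.uniform(-2, 2, (2, 3)), V=rng.uniform(-1, 1, 2))
        X = rng.random((20, 3))
        batch = forward_batch(X, arch, params)
        single = [forward(x, arch, params) for x in X]
        np.testing.assert_allclose(batch, single, atol=1e-12)

    def test_output_strictly_inside_unit_interval(self, rng):
        arch = QDNNArchitecture(N=2, M=2)
        params = QDNNParams(W=rng.uniform(-3, 3, (2, 2)), V=rng.uniform(-5, 5, 2))
        y = forward_batch(rng.random((50, 2)), arch, params)
        assert (y > 0).all() and (y < 1).all()

    def test_deterministic(self, rng):
        arch = QDNNArchitecture(N=2, M=1)
        params = QDNNParams(W=rng.uniform(-1, 1, (1, 2)), V=[0.7])
        x = rng.random(2)
        assert forward(x, arch, params) == forward(x, arch, params)

    def test_architecture_guard(self):
        with pytest.raises(ValueError):
            QDNNArchitecture(N=10, M=5)


class TestLosses:
    @pytest.mark.parametrize("y,p,expected", [
        (1, 0.5, math.log(2)), (0, 0.5, math.log(2)), (1, 1.0, 0.0)])
    def test_bce_closed_forms(self, y, p, expected):
        assert bce_loss(y, p) == pytest.approx(expected, abs=1e-9)

    def test_bce_total_via_clipping(self):
        assert math.isfinite(bce_loss(1, 0.0))
        assert bce_loss(1, 0.0) > 20

    def test_mean_loss_two_point(self):
        assert mean_loss([1, 1], [1.0, 0.5]) == pytest.approx(math.log(2) / 2, abs=1e-9)

    def test_mean_loss_matches_sum_oracle(self, rng):
        y = rng.integers(0, 2, 100)
        p = rng.uniform(0.01, 0.99, 100)
        want = sum(bce_loss(int(yi), pi) for yi, pi in zip(y, p)) / 100
        assert mean_loss(y, p) == pytest.approx(want, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_loss([], [])


class TestMulticlass:
    def test_argmax_and_tie_break(self, rng):
        arch = QDNNArchitecture(N=2, M=1)
        hi = QDNNParams(W=np.array([[-math.pi / 2, 0.0]]), V=np.array([3.0]))
        lo = QDNNParams(W=np.zeros((1, 2)), V=np.array([0.0]))
        # head 1 responds strongly to feature 0 near 0
        assert predict_multiclass(np.array([0.0, 0.5]), arch, [lo, hi]) == 1
        assert predict_multiclass(np.array([0.0, 0.5]), arch, [lo, lo]) == 0

    def test_requires_two_heads(self):
        arch = QDNNArchitecture(N=1, M=1)
        head = QDNNParams(W=np.zeros((1, 1)), V=np.zeros(1))
        with pytest.raises(ValueError):
            predict_multiclass(np.array([0.5]), arch, [head])
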