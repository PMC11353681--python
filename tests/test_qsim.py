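"""Statevector simulator: gate matrices, circuit execution, Pauli-Z
expectations, and gradients, all checked against independent oracles
(dense Kronecker-product matrices, closed forms, finite differences)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quanvnet import qsim
from quanvnet.qsim import CircuitSpec, GateOp, PureState

from conftest import dense_unitary

ALL_GATES = ["X", "Y", "Z", "H", "S", "RX", "RY", "RZ", "U3", "CNOT"]


def random_gate(rng, n_qubits):
    name = rng.choice(ALL_GATES)
    n_params = {"RX": 1, "RY": 1, "RZ": 1, "U3": 3}.get(name, 0)
    params = tuple(rng.uniform(-np.pi, np.pi, n_params))
    n_wires = 2 if name == "CNOT" else 1
    wires = tuple(rng.choice(n_qubits, size=n_wires, replace=False))
    return GateOp(name, wires, params)


def random_state(rng, n):
    amps = rng.normal(size=2**n) + 1j * rng.normal(size=2**n)
    return PureState(n, amps / np.linalg.norm(amps))


class TestGateMatrix:
    def test_u3_zero_angles_is_identity(self):
        assert np.allclose(qsim.gate_matrix("U3", [0, 0, 0]), np.eye(2))

    def test_cnot_permutation(self):
        expected = np.array([[1, 0, 0, 0], [0, 1, 0, 0],
                             [0, 0, 0, 1], [0, 0, 1, 0]])
        assert np.array_equal(qsim.gate_matrix("CNOT"), expected)

    def test_ry_pi(self):
        assert np.allclose(qsim.gate_matrix("RY", [np.pi]), [[0, -1], [1, 0]],
                           atol=1e-15)

    @pytest.mark.parametrize("name", ALL_GATES)
    def test_unitarity(self, name, rng):
        n_params = {"RX": 1, "RY": 1, "RZ": 1, "U3": 3}.get(name, 0)
        for _ in range(5):
            params = rng.uniform(-2 * np.pi, 2 * np.pi, n_params)
            u = qsim.gate_matrix(name, params)
            assert np.allclose(u @ u.conj().T, np.eye(len(u)), atol=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            qsim.gate_matrix("TOFFOLI")
        with pytest.raises(ValueError):
            qsim.gate_matrix("RX", [])
        with pytest.raises(ValueError):
            qsim.gate_matrix("H", [0.3])


class TestPureState:
    def test_normalization_enforced(self):
        with pytest.raises(ValueError):
            PureState(1, np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            PureState(2, np.array([1.0, 0.0]))

    def test_zero_state(self):
        s = PureState.zero(3)
        assert s.amplitudes[0] == 1.0
        assert np.sum(np.abs(s.amplitudes) ** 2) == pytest.approx(1.0)


class TestApplyGate:
    def test_x_flips_zero(self):
        out = qsim.apply_gate(PureState.zero(1), GateOp("X", (0,)))
        assert np.allclose(out.amplitudes, [0, 1])

    def test_cnot_on_10(self):
        # control qubit 0 set -> target flips: |10> -> |11>
        out = qsim.apply_gate(PureState.from_bits([1, 0]), GateOp("CNOT", (0, 1)))
        assert np.allclose(out.amplitudes, [0, 0, 0, 1])

    def test_wire_out_of_range(self):
        with pytest.raises(IndexError):
            qsim.apply_gate(PureState.zero(2), GateOp("X", (5,)))

    @pytest.mark.parametrize("n", [2, 4, 9])
    def test_matches_dense_oracle(self, n, rng):
        """Gate-wise tensor contraction equals multiplication by the full
        2^n x 2^n unitary built by explicit Kronecker products."""
        for _ in range(3 if n == 9 else 6):
            state = random_state(rng, n)
            op = random_gate(rng, n)
            full = dense_unitary(qsim.gate_matrix(op.name, op.params),
                                 op.wires, n)
            expected = full @ state.amplitudes
            got = qsim.apply_gate(state, op).amplitudes
            assert np.allclose(got, expected, atol=1e-10)

    def test_norm_preserved(self, rng):
        state = random_state(rng, 5)
        for _ in range(30):
            state = qsim.apply_gate(state, random_gate(rng, 5))
        assert np.sum(np.abs(state.amplitudes) ** 2) == pytest.approx(1.0,
                                                                      abs=1e-10)


class TestRunCircuit:
    def test_empty_circuit_identity(self, rng):
        state = random_state(rng, 3)
        out = qsim.run_circuit(CircuitSpec(3), initial=state)
        assert np.allclose(out.amplitudes, state.amplitudes)

    def test_double_x_is_identity(self, rng):
        state = random_state(rng, 2)
        spec = CircuitSpec(2, [GateOp("X", (0,)), GateOp("X", (0,))])
        out = qsim.run_circuit(spec, initial=state)
        assert np.allclose(out.amplitudes, state.amplitudes, atol=1e-12)

    def test_random_circuit_matches_dense_product(self, rng):
        """20 random gates on 9 qubits: product of dense unitaries."""
        n = 9
        ops = [random_gate(rng, n) for _ in range(20)]
        spec = CircuitSpec(n, ops)
        state = random_state(rng, n)
        full = np.eye(2**n, dtype=complex)
        for op in ops:
            full = dense_unitary(qsim.gate_matrix(op.name, op.params),
                                 op.wires, n) @ full
        expected = full @ state.amplitudes
        got = qsim.run_circuit(spec, initial=state).amplitudes
        assert np.allclose(got, expected, atol=1e-10)

    def test_value_length_mismatch(self):
        spec = CircuitSpec(1, [GateOp("RX", (0,), (0.0,))], {0: [(0, 0)]})
        with pytest.raises(ValueError):
            qsim.run_circuit(spec, [0.1, 0.2])


class TestExpvalZ:
    def test_basis_states(self):
        assert qsim.expval_z(PureState.from_bits([0]), 0) == pytest.approx(1.0)
        assert qsim.expval_z(PureState.from_bits([1]), 0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("theta", [0.3, 1.0, np.pi / 2])
    def test_rx_closed_form(self, theta):
        """<Z> after RX(theta) on |0> equals cos(theta)."""
        spec = CircuitSpec(1, [GateOp("RX", (0,), (0.0,))], {0: [(0, 0)]})
        out = qsim.run_circuit(spec, [theta])
        assert qsim.expval_z(out, 0) == pytest.approx(np.cos(theta), abs=1e-12)

    def test_bounded(self, rng):
        for _ in range(10):
            state = random_state(rng, 4)
            for w in range(4):
                assert -1.0 <= qsim.expval_z(state, w) <= 1.0

    def test_wire_out_of_range(self):
        with pytest.raises(IndexError):
            qsim.expval_z(PureState.zero(2), 2)


class TestGradients:
    def test_single_rx_closed_form(self):
        """d<Z>/dtheta = -sin(theta) for RX(theta)|0>."""
        spec = CircuitSpec(1, [GateOp("RX", (0,), (0.0,))], {0: [(0, 0)]})
        g = qsim.grad_param_shift(spec, [0.7], 0)
        assert g[0] == pytest.approx(-np.sin(0.7), abs=1e-12)
        assert qsim.grad_param_shift(spec, [0.0], 0)[0] == pytest.approx(0.0,
                                                                         abs=1e-12)

    def test_nondifferentiable_gate_rejected(self):
        spec = CircuitSpec(1, [GateOp("RX", (0,), (0.0,)), GateOp("H", (0,))],
                           {0: [(0, 0)]})
        qsim.grad_param_shift(spec, [0.3], 0)  # H unbound: fine
        bad = CircuitSpec(1, [GateOp("H", (0,))], {0: []})
        with pytest.raises(ValueError):
            qsim.grad_param_shift(bad, [], 0)

    def _random_trainable_circuit(self, rng, n, n_gates, n_slots):
        """Random gates; trainable angle positions are assigned to slots
        round-robin, so every slot is fed and several positions share a
        slot (parameter sharing) without double-binding any position."""
        ops = []
        positions = []
        for i in range(n_gates):
            name = rng.choice(["RX", "RY", "RZ", "U3", "CNOT", "H"])
            if name == "CNOT":
                wires = tuple(rng.choice(n, size=2, replace=False))
                ops.append(GateOp("CNOT", wires))
            elif name == "H":
                ops.append(GateOp("H", (int(rng.integers(n)),)))
            else:
                n_p = 3 if name == "U3" else 1
                params = tuple(rng.uniform(-np.pi, np.pi, n_p))
                ops.append(GateOp(name, (int(rng.integers(n)),), params))
                positions.extend((i, pos) for pos in range(n_p))
        assert len(positions) >= n_slots
        bindings = {s: [] for s in range(n_slots)}
        for j, key in enumerate(positions):
            bindings[j % n_slots].append(key)
        return CircuitSpec(n, ops, bindings)

    def test_param_shift_matches_finite_differences(self, rng):
        """15-slot random circuit with parameter sharing: shift-rule
        gradients agree with central finite differences to 1e-6."""
        spec = self._random_trainable_circuit(rng, 4, 25, 15)
        values = rng.uniform(-np.pi, np.pi, 15)
        wire = 2
        g = qsim.grad_param_shift(spec, values, wire)
        h = 1e-6
        for k in range(15):
            vp, vm = values.copy(), values.copy()
            vp[k] += h
            vm[k] -= h
            fp = qsim.expval_z(qsim.run_circuit(spec, vp), wire)
            fm = qsim.expval_z(qsim.run_circuit(spec, vm), wire)
            assert g[k] == pytest.approx((fp - fm) / (2 * h), abs=1e-6)

    def test_backprop_matches_param_shift(self, rng):
        spec = self._random_trainable_circuit(rng, 4, 20, 8)
        values = rng.uniform(-np.pi, np.pi, 8)
        for wire in (0, 3):
            ps = qsim.grad_param_shift(spec, values, wire)
            bp = qsim.grad_backprop(spec, values, {wire: 1.0})
            assert np.allclose(ps, bp, atol=1e-10)


class TestSerialization:
    def test_round_trip(self, rng):
        ops = [GateOp("U3", (0,), (0.1, 0.2, 0.3)),
               GateOp("CNOT", (1, 0)),
               GateOp("RX", (2,), (0.5,)),
               GateOp("H", (1,))]
        spec = CircuitSpec(3, ops, {0: [(0, 0), (2, 0)], 1: [(0, 2)]})
        text = spec.to_text()
        back = CircuitSpec.from_text(text)
        assert back.n_qubits == 3
        assert back.ops[1] == GateOp("CNOT", (1, 0))
        assert back.param_bindings == spec.param_bindings
        values = rng.uniform(-1, 1, 2)
        a = qsim.run_circuit(spec, values).amplitudes
        b = qsim.run_circuit(back, values).amplitudes
        assert np.allclose(a, b, atol=1e-12)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(theta=st.floats(-10, 10), wire=st.integers(0, 2))
def test_norm_conservation_property(theta, wire):
    """Any rotation applied anywhere preserves the state norm to 1e-10."""
    state = PureState.zero(3)
    state = qsim.apply_gate(state, GateOp("H", (wire,)))
    state = qsim.apply_gate(state, GateOp("RY", ((wire + 1) % 3,), (theta,)))
    state = qsim.apply_gate(state, GateOp("CNOT", (wire, (wire + 1) % 3)))
    assert np.sum(np.abs(state.amplitudes) ** 2) == pytest.approx(1.0, abs=1e-10)
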