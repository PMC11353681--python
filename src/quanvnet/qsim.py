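"""Exact statevector simulation of few-qubit parameterized circuits.

The register state of ``n`` qubits is a normalized complex vector of
length ``2**n``.  Basis ordering convention: **qubit 0 is the most
significant bit** of the basis index, so for two qubits the basis is
|00>, |01>, |10>, |11> with qubit 0 the left bit.  All gates are exact
complex-double unitaries; there is no shot noise and no noise model.

Gradients of Pauli-Z expectation values are available both through the
parameter-shift rule (:func:`grad_param_shift`) and through reverse-mode
differentiation of the statevector (:func:`grad_backprop`); the two agree
to numerical precision and with finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PureState",
    "GateOp",
    "CircuitSpec",
    "gate_matrix",
    "apply_gate",
    "run_circuit",
    "expval_z",
    "grad_param_shift",
    "grad_backprop",
]

_SQ2 = 1.0 / np.sqrt(2.0)

# Fixed (parameter-free) gate matrices.
_FIXED = {
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
    "H": np.array([[_SQ2, _SQ2], [_SQ2, -_SQ2]], dtype=complex),
    "S": np.array([[1, 0], [0, 1j]], dtype=complex),
    # control = first wire: |10> -> |11>, |11> -> |10>
    "CNOT": np.array(
        [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=complex
    ),
}

_N_PARAMS = {"X": 0, "Y": 0, "Z": 0, "H": 0, "S": 0, "CNOT": 0,
             "RX": 1, "RY": 1, "RZ": 1, "U3": 3}
_N_WIRES = {name: (2 if name == "CNOT" else 1) for name in _N_PARAMS}


def gate_matrix(name: str, params=()) -> np.ndarray:
    """Return the unitary matrix of a named gate (2x2, or 4x4 for CNOT).

    Angles are in radians.  RX/RY/RZ take one angle; U3 takes
    (theta, phi, lam) and equals the standard arbitrary single-qubit
    rotation ``[[cos t/2, -e^{i lam} sin t/2],
    [e^{i phi} sin t/2, e^{i(lam+phi)} cos t/2]]``.
    """
    name = name.upper()
    if name not in _N_PARAMS:
        raise ValueError(f"unknown gate name: {name!r}")
    params = tuple(float(p) for p in params)
    if len(params) != _N_PARAMS[name]:
        raise ValueError(
            f"gate {name} takes {_N_PARAMS[name]} parameter(s), got {len(params)}"
        )
    if name in _FIXED:
        return _FIXED[name].copy()
    if name == "RX":
        (t,) = params
        c, s = np.cos(t / 2), np.sin(t / 2)
        return np.array([[c, -1j * s], [-1j * s, c]])
    if name == "RY":
        (t,) = params
        c, s = np.cos(t / 2), np.sin(t / 2)
        return np.array([[c, -s], [s, c]], dtype=complex)
    if name == "RZ":
        (t,) = params
        return np.array([[np.exp(-1j * t / 2), 0], [0, np.exp(1j * t / 2)]])
    # U3
    t, phi, lam = params
    c, s = np.cos(t / 2), np.sin(t / 2)
    return np.array(
        [
            [c, -np.exp(1j * lam) * s],
            [np.exp(1j * phi) * s, np.exp(1j * (lam + phi)) * c],
        ]
    )


def gate_matrix_deriv(name: str, params, which: int) -> np.ndarray:
    """d(gate_matrix)/d(params[which]) — analytic, used by reverse mode."""
    name = name.upper()
    params = tuple(float(p) for p in params)
    if name == "RX":
        (t,) = params
        c, s = np.cos(t / 2), np.sin(t / 2)
        return 0.5 * np.array([[-s, -1j * c], [-1j * c, -s]])
    if name == "RY":
        (t,) = params
        c, s = np.cos(t / 2), np.sin(t / 2)
        return 0.5 * np.array([[-s, -c], [c, -s]], dtype=complex)
    if name == "RZ":
        (t,) = params
        return 0.5 * np.array(
            [[-1j * np.exp(-1j * t / 2), 0], [0, 1j * np.exp(1j * t / 2)]]
        )
    if name == "U3":
        t, phi, lam = params
        c, s = np.cos(t / 2), np.sin(t / 2)
        if which == 0:
            return 0.5 * np.array(
                [
                    [-s, -np.exp(1j * lam) * c],
                    [np.exp(1j * phi) * c, -np.exp(1j * (lam + phi)) * s],
                ]
            )
        if which == 1:
            return np.array(
                [
                    [0, 0],
                    [1j * np.exp(1j * phi) * s, 1j * np.exp(1j * (lam + phi)) * c],
                ]
            )
        if which == 2:
            return np.array(
                [
                    [0, -1j * np.exp(1j * lam) * s],
                    [0, 1j * np.exp(1j * (lam + phi)) * c],
                ]
            )
    raise ValueError(f"gate {name} has no differentiable parameter {which}")


@dataclass
class PureState:
    """Normalized complex amplitude vector over ``n_qubits`` qubits.

    Qubit 0 is the most significant bit of the basis index.
    """

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self):
        if not (1 <= self.n_qubits <= 12):
            raise ValueError("n_qubits must be in 1..12")
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex).ravel()
        if self.amplitudes.size != 2**self.n_qubits:
            raise ValueError(
                f"amplitude vector length {self.amplitudes.size} != 2**{self.n_qubits}"
            )
        norm = np.sum(np.abs(self.amplitudes) ** 2)
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"state not normalized: |psi|^2 = {norm}")

    @classmethod
    def zero(cls, n_qubits: int) -> "PureState":
        """The all-|0> computational basis state."""
        amps = np.zeros(2**n_qubits, dtype=complex)
        amps[0] = 1.0
        return cls(n_qubits, amps)

    @classmethod
    def from_bits(cls, bits) -> "PureState":
        """Basis state |b0 b1 ... >, qubit 0 first."""
        bits = list(bits)
        idx = 0
        for b in bits:
            idx = (idx << 1) | int(b)
        amps = np.zeros(2 ** len(bits), dtype=complex)
        amps[idx] = 1.0
        return cls(len(bits), amps)


@dataclass(frozen=True)
class GateOp:
    """One gate application: name, ordered wires (control first for CNOT),
    and literal angle parameters in radians."""

    name: str
    wires: tuple
    params: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "name", self.name.upper())
        object.__setattr__(self, "wires", tuple(int(w) for w in self.wires))
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.name not in _N_PARAMS:
            raise ValueError(f"unknown gate name: {self.name!r}")
        if len(self.wires) != _N_WIRES[self.name]:
            raise ValueError(f"gate {self.name} takes {_N_WIRES[self.name]} wire(s)")
        if len(set(self.wires)) != len(self.wires):
            raise ValueError("wires must be distinct")
        if len(self.params) != _N_PARAMS[self.name]:
            raise ValueError(
                f"gate {self.name} takes {_N_PARAMS[self.name]} parameter(s)"
            )


@dataclass
class CircuitSpec:
    """Ordered gate list plus trainable-parameter bindings.

    ``param_bindings`` maps a trainable slot index to the list of
    ``(op_index, angle_position)`` pairs it feeds; several positions may
    share one slot (parameter sharing).  Unbound angle positions keep the
    literal value stored in the op.
    """

    n_qubits: int
    ops: list = field(default_factory=list)
    param_bindings: dict = field(default_factory=dict)

    @property
    def n_slots(self) -> int:
        return len(self.param_bindings)

    def validate(self):
        for op in self.ops:
            for w in op.wires:
                if not (0 <= w < self.n_qubits):
                    raise IndexError(f"wire {w} out of range for {self.n_qubits} qubits")
        for slot, positions in self.param_bindings.items():
            if not positions:
                raise ValueError(f"trainable slot {slot} feeds no angle position")
            for op_idx, pos in positions:
                if not (0 <= op_idx < len(self.ops)):
                    raise ValueError(f"slot {slot} bound to missing op {op_idx}")
                if not (0 <= pos < len(self.ops[op_idx].params)):
                    raise ValueError(
                        f"slot {slot} bound to missing angle position {pos} "
                        f"of op {op_idx}"
                    )
        expected = set(range(self.n_slots))
        if set(self.param_bindings) != expected:
            raise ValueError("trainable slots must be numbered 0..n_slots-1")
        seen = set()
        for positions in self.param_bindings.values():
            for key in positions:
                if tuple(key) in seen:
                    raise ValueError(
                        f"angle position {key} bound to more than one slot")
                seen.add(tuple(key))

    def resolved_params(self, values) -> list:
        """Per-op angle tuples with slot values substituted in."""
        values = np.asarray(values, dtype=float).ravel()
        if values.size != self.n_slots:
            raise ValueError(
                f"expected {self.n_slots} trainable values, got {values.size}"
            )
        resolved = [list(op.params) for op in self.ops]
        for slot, positions in self.param_bindings.items():
            for op_idx, pos in positions:
                resolved[op_idx][pos] = values[slot]
        return [tuple(p) for p in resolved]

    # -- line-oriented text serialization --------------------------------
    # one gate per line: NAME wire[,wire] [slot:k | lit:v]...

    def to_text(self) -> str:
        slot_of = {}
        for slot, positions in self.param_bindings.items():
            for op_idx, pos in positions:
                slot_of[(op_idx, pos)] = slot
        lines = [f"# qubits {self.n_qubits}"]
        for i, op in enumerate(self.ops):
            tokens = [op.name, ",".join(str(w) for w in op.wires)]
            for pos, val in enumerate(op.params):
                if (i, pos) in slot_of:
                    tokens.append(f"slot:{slot_of[(i, pos)]}")
                else:
                    tokens.append(f"lit:{val!r}")
            lines.append(" ".join(tokens))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CircuitSpec":
        n_qubits = None
        ops = []
        bindings: dict = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "qubits":
                    n_qubits = int(parts[1])
                continue
            tokens = line.split()
            name = tokens[0].upper()
            wires = tuple(int(w) for w in tokens[1].split(","))
            params = []
            for pos, tok in enumerate(tokens[2:]):
                kind, _, val = tok.partition(":")
                if kind == "slot":
                    bindings.setdefault(int(val), []).append((len(ops), pos))
                    params.append(0.0)
                elif kind == "lit":
                    params.append(float(val))
                else:
                    raise ValueError(f"bad parameter token {tok!r}")
            ops.append(GateOp(name, wires, tuple(params)))
        if n_qubits is None:
            n_qubits = 1 + max((w for op in ops for w in op.wires), default=0)
        spec = cls(n_qubits, ops, bindings)
        spec.validate()
        return spec


# ---------------------------------------------------------------------------
# Low-level engine: gate application on (batched) amplitude arrays.


def apply_unitary(amps: np.ndarray, mat: np.ndarray, wires, n_qubits: int) -> np.ndarray:
    """Apply ``mat`` on the given wires of ``amps`` with shape (..., 2**n).

    ``mat`` may be (m, m) or batched (B, m, m) matching the leading axis of
    ``amps``.  Returns a new array; the input is not modified.
    """
    wires = tuple(wires)
    k = len(wires)
    lead = amps.shape[:-1]
    t = amps.reshape((-1,) + (2,) * n_qubits)
    src = [1 + w for w in wires]
    dst = list(range(1, 1 + k))
    t = np.moveaxis(t, src, dst)
    rest_shape = t.shape
    t = t.reshape(t.shape[0], 2**k, -1)
    out = mat @ t  # (m,m)@(B,m,R) or (B,m,m)@(B,m,R)
    out = out.reshape(rest_shape)
    out = np.moveaxis(out, dst, src)
    return out.reshape(lead + (2**n_qubits,))


def apply_gate(state: PureState, op: GateOp) -> PureState:
    """Return U|psi> for a single gate, by tensor contraction on its wires."""
    for w in op.wires:
        if not (0 <= w < state.n_qubits):
            raise IndexError(f"wire {w} out of range for {state.n_qubits} qubits")
    mat = gate_matrix(op.name, op.params)
    amps = apply_unitary(state.amplitudes, mat, op.wires, state.n_qubits)
    return PureState(state.n_qubits, amps)


def run_circuit(spec: CircuitSpec, values=(), initial: PureState | None = None) -> PureState:
    """Apply the circuit's gates in listed order to ``initial`` (default |0..0>)."""
    spec.validate()
    if initial is None:
        initial = PureState.zero(spec.n_qubits)
    if initial.n_qubits != spec.n_qubits:
        raise ValueError("initial state qubit count does not match circuit")
    resolved = spec.resolved_params(values)
    amps = initial.amplitudes
    for op, params in zip(spec.ops, resolved):
        mat = gate_matrix(op.name, params)
        amps = apply_unitary(amps, mat, op.wires, spec.n_qubits)
    return PureState(spec.n_qubits, amps)


def z_signs(n_qubits: int, wire: int) -> np.ndarray:
    """Diagonal of Z on ``wire``: +1 where the wire bit is 0, −1 where 1."""
    idx = np.arange(2**n_qubits)
    bit = (idx >> (n_qubits - 1 - wire)) & 1
    return 1.0 - 2.0 * bit


def expval_z(state: PureState, wire: int) -> float:
    """<psi| Z_wire |psi> — probability-weighted ±1, always in [−1, 1]."""
    if not (0 <= wire < state.n_qubits):
        raise IndexError(f"wire {wire} out of range")
    probs = np.abs(state.amplitudes) ** 2
    return float(np.dot(probs, z_signs(state.n_qubits, wire)))


_SHIFTABLE = {"RX", "RY", "RZ", "U3"}


def grad_param_shift(spec: CircuitSpec, values, wire: int,
                     initial: PureState | None = None) -> np.ndarray:
    """Parameter-shift gradient of <Z_wire> w.r.t. each trainable slot.

    Each angle position contributes ``[f(a + pi/2) − f(a − pi/2)] / 2``;
    positions sharing a slot accumulate.  Valid because every trainable
    gate (RX/RY/RZ and each U3 angle separately) enters the expectation
    as a single-frequency sinusoid.
    """
    spec.validate()
    values = np.asarray(values, dtype=float).ravel()
    for slot, positions in spec.param_bindings.items():
        for op_idx, _ in positions:
            if spec.ops[op_idx].name not in _SHIFTABLE:
                raise ValueError(
                    f"gate {spec.ops[op_idx].name} in trainable slot {slot} "
                    "does not admit the parameter-shift rule"
                )
    base = spec.resolved_params(values)

    def f_with(op_idx, pos, angle):
        if initial is None:
            amps = np.zeros(2**spec.n_qubits, dtype=complex)
            amps[0] = 1.0
        else:
            amps = initial.amplitudes.copy()
        for j, op in enumerate(spec.ops):
            params = list(base[j])
            if j == op_idx:
                params[pos] = angle
            amps = apply_unitary(amps, gate_matrix(op.name, params), op.wires,
                                 spec.n_qubits)
        probs = np.abs(amps) ** 2
        return float(np.dot(probs, z_signs(spec.n_qubits, wire)))

    grad = np.zeros(spec.n_slots)
    for slot, positions in spec.param_bindings.items():
        for op_idx, pos in positions:
            a = base[op_idx][pos]
            grad[slot] += (f_with(op_idx, pos, a + np.pi / 2)
                           - f_with(op_idx, pos, a - np.pi / 2)) / 2.0
    return grad


def grad_backprop(spec: CircuitSpec, values, out_grads: dict,
                  initial: PureState | None = None) -> np.ndarray:
    """Reverse-mode gradient of ``sum_w out_grads[w] * <Z_w>`` w.r.t. slots.

    One forward pass storing intermediate states, one adjoint sweep; cost
    is a small multiple of a single circuit execution regardless of the
    number of trainable slots.
    """
    spec.validate()
    n = spec.n_qubits
    resolved = spec.resolved_params(values)
    amps = (PureState.zero(n) if initial is None else initial).amplitudes
    states = [amps]
    mats = []
    for op, params in zip(spec.ops, resolved):
        mat = gate_matrix(op.name, params)
        mats.append(mat)
        amps = apply_unitary(amps, mat, op.wires, n)
        states.append(amps)

    # lambda = dL/d(psi*) at the circuit output
    lam = np.zeros_like(amps)
    for wire, g in out_grads.items():
        lam = lam + g * z_signs(n, wire) * amps

    pos_to_slot = {}
    for slot, positions in spec.param_bindings.items():
        for op_idx, pos in positions:
            pos_to_slot[(op_idx, pos)] = slot

    grad = np.zeros(spec.n_slots)
    for j in range(len(spec.ops) - 1, -1, -1):
        op = spec.ops[j]
        psi_prev = states[j]
        for pos in range(len(op.params)):
            slot = pos_to_slot.get((j, pos))
            if slot is None:
                continue
            dmat = gate_matrix_deriv(op.name, resolved[j], pos)
            dpsi = apply_unitary(psi_prev, dmat, op.wires, n)
            grad[slot] += 2.0 * float(np.real(np.vdot(lam, dpsi)))
        lam = apply_unitary(lam, mats[j].conj().T, op.wires, n)
    return grad
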