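"""Quanvolution: quantum circuits as 3x3 convolutional kernels.

A 3x3 image patch (9 pixels in [0, 1]) is angle-embedded onto 9 qubits —
pixel value ``p`` becomes an RX rotation by ``p * pi/2``, mapping the
pixel range onto rotation angles in [0, pi/2].  The embedded state is
then processed by a strongly entangling 15-parameter kernel circuit and
measured in the Pauli-Z basis, producing nine expectation values in
[−1, 1]: the nine channels of one output pixel.  Sliding the kernel over
the image with stride 2 and no padding yields the feature map.

The kernel circuit applies one SU(4)-style two-qubit block to each
adjacent qubit pair (0,1), (1,2), ..., (7,8).  Each block is the standard
three-CNOT decomposition of an arbitrary two-qubit unitary — U3 on both
qubits, CNOT, RZ/RY, CNOT, RY, CNOT, U3 on both qubits — and all eight
blocks **share** the same 15 angles, so one kernel exposes exactly 15
trainable parameters no matter how many qubit pairs it entangles.

Besides the spec-level operations built on :mod:`quanvnet.qsim`, this
module houses a batched execution path (``quanvolve_batch`` /
``quanvolve_batch_backward``) that simulates all patches of a minibatch
simultaneously on a (B, 512) amplitude array and differentiates through
the statevector in reverse mode.  The batched path is checked against the
gate-by-gate path and a dense-unitary oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qsim import (
    CircuitSpec,
    GateOp,
    PureState,
    apply_unitary,
    gate_matrix,
    gate_matrix_deriv,
    run_circuit,
    z_signs,
)

__all__ = [
    "Patch",
    "KernelParams",
    "FeatureMap",
    "encode_patch",
    "build_kernel",
    "quanvolve_patch",
    "quanvolve_image",
    "rescale_map",
    "quanv_layer2",
    "quanvolve_batch",
    "quanvolve_batch_backward",
]

N_QUBITS = 9
N_KERNEL_PARAMS = 15
KERNEL_SIZE = 3
STRIDE = 2
_DIM = 2**N_QUBITS

# (9, 512) matrix of Z diagonals; <Z_w> = _ZSIGNS[w] . |psi|^2
_ZSIGNS = np.stack([z_signs(N_QUBITS, w) for w in range(N_QUBITS)])


@dataclass(frozen=True)
class Patch:
    """A 3x3 block of pixels in [0, 1], row-major."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"patch must be 3x3, got {v.shape}")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("patch values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class KernelParams:
    """The 15 trainable angles (radians) of one quanvolutional kernel."""

    theta: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.theta, dtype=float).ravel()
        if t.size != N_KERNEL_PARAMS:
            raise ValueError(f"kernel takes {N_KERNEL_PARAMS} angles, got {t.size}")
        object.__setattr__(self, "theta", t)


@dataclass
class FeatureMap:
    """H x W x C tensor of Pauli-Z expectations (or their [0,1] rescaling)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("feature map must be H x W x C")
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]

    def to_csv(self, path) -> None:
        """One row per spatial cell: r,c,ch0..chN."""
        h, w, c = self.values.shape
        with open(path, "w") as fh:
            fh.write("r,c," + ",".join(f"ch{i}" for i in range(c)) + "\n")
            for r in range(h):
                for col in range(w):
                    vals = ",".join(repr(float(v)) for v in self.values[r, col])
                    fh.write(f"{r},{col},{vals}\n")


def encode_patch(patch: Patch) -> CircuitSpec:
    """Angle-embedding prefix: RX(p * pi/2) on qubit i for pixel i.

    Qubit i carries pixel (row i // 3, col i % 3); a pixel of 1.0 rotates
    by pi/2, taking <Z> from +1 down to cos(pi/2) = 0.
    """
    flat = patch.values.ravel()
    ops = [GateOp("RX", (i,), (float(v) * np.pi / 2,)) for i, v in enumerate(flat)]
    return CircuitSpec(N_QUBITS, ops, {})


# slot layout of one SU(4) pair-block, shared across all 8 blocks:
#   U3(p0,p1,p2) q_a | U3(p3,p4,p5) q_b | CNOT b->a | RZ(p6) a | RY(p7) b
#   | CNOT a->b | RY(p8) b | CNOT b->a | U3(p9,p10,p11) a | U3(p12,p13,p14) b
_BLOCK = [
    ("U3", "a", (0, 1, 2)),
    ("U3", "b", (3, 4, 5)),
    ("CNOT", ("b", "a"), ()),
    ("RZ", "a", (6,)),
    ("RY", "b", (7,)),
    ("CNOT", ("a", "b"), ()),
    ("RY", "b", (8,)),
    ("CNOT", ("b", "a"), ()),
    ("U3", "a", (9, 10, 11)),
    ("U3", "b", (12, 13, 14)),
]


def build_kernel(params: KernelParams) -> CircuitSpec:
    """The 9-qubit entangling kernel: 8 shared SU(4) blocks, 80 gates,
    exactly 15 trainable slots."""
    theta = params.theta
    ops = []
    bindings: dict = {s: [] for s in range(N_KERNEL_PARAMS)}
    for pair in range(N_QUBITS - 1):
        qubit = {"a": pair, "b": pair + 1}
        for name, wires, slots in _BLOCK:
            if name == "CNOT":
                ops.append(GateOp("CNOT", (qubit[wires[0]], qubit[wires[1]])))
            else:
                angles = tuple(theta[s] for s in slots)
                op_idx = len(ops)
                ops.append(GateOp(name, (qubit[wires],), angles))
                for pos, s in enumerate(slots):
                    bindings[s].append((op_idx, pos))
    spec = CircuitSpec(N_QUBITS, ops, bindings)
    spec.validate()
    return spec


def quanvolve_patch(patch: Patch, params: KernelParams) -> np.ndarray:
    """Encode one patch, run the kernel on |0..0>, return the nine <Z_w>."""
    enc = encode_patch(patch)
    kern = build_kernel(params)
    spec = CircuitSpec(N_QUBITS, enc.ops + kern.ops,
                       {s: [(i + len(enc.ops), p) for i, p in pos]
                        for s, pos in kern.param_bindings.items()})
    state = run_circuit(spec, params.theta)
    probs = np.abs(state.amplitudes) ** 2
    return _ZSIGNS @ probs


def _extract_patches(image: np.ndarray) -> tuple[np.ndarray, int, int]:
    """All 3x3 stride-2 windows, flattened: (n_windows, 9) plus (H_out, W_out)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    h, w = image.shape
    if h < KERNEL_SIZE or w < KERNEL_SIZE:
        raise ValueError(f"image {h}x{w} smaller than {KERNEL_SIZE}x{KERNEL_SIZE} kernel")
    h_out = (h - KERNEL_SIZE) // STRIDE + 1
    w_out = (w - KERNEL_SIZE) // STRIDE + 1
    patches = np.empty((h_out * w_out, KERNEL_SIZE * KERNEL_SIZE))
    k = 0
    for r in range(h_out):
        for c in range(w_out):
            patches[k] = image[STRIDE * r:STRIDE * r + 3,
                               STRIDE * c:STRIDE * c + 3].ravel()
            k += 1
    return patches, h_out, w_out


def quanvolve_image(image, params: KernelParams, kernel: int = 3,
                    stride: int = 2) -> FeatureMap:
    """Slide the quantum kernel over the image (stride 2, no padding).

    Output spatial size is ``floor((H-3)/2)+1 x floor((W-3)/2)+1`` with 9
    channels; the window at output (r, c) covers input rows 2r..2r+2 and
    columns 2c..2c+2.
    """
    if kernel != KERNEL_SIZE or stride != STRIDE:
        raise ValueError("only the 3x3 / stride-2 configuration is supported")
    image = np.asarray(image, dtype=float)
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    patches, h_out, w_out = _extract_patches(image)
    z, _ = quanvolve_batch(patches, params.theta)
    return FeatureMap(z.reshape(h_out, w_out, N_QUBITS))


def rescale_map(fm: FeatureMap) -> FeatureMap:
    """Map expectation values from [−1, 1] to [0, 1]: v -> (v + 1) / 2."""
    v = fm.values
    if v.min() < -1.0 - 1e-12 or v.max() > 1.0 + 1e-12:
        raise ValueError("feature map values must lie in [-1, 1]")
    return FeatureMap((v + 1.0) / 2.0)


def quanv_layer2(fm: FeatureMap, params2: KernelParams,
                 mode: str = "stacked") -> FeatureMap:
    """Second quanvolution over a rescaled (values in [0,1]) feature map.

    ``stacked`` (default): each spatial cell's 9 channel values are
    re-encoded directly as one 9-qubit register and passed through the
    shared second kernel, keeping the spatial shape (6x6x9 -> 6x6x9).
    ``spatial``: each input channel is treated as its own image and
    quanvolved (3x3, stride 2), so a 6x6x9 map becomes 2x2x81 — output
    channel ``c*9 + k`` holds wire ``k`` of input channel ``c``.  Both
    feed 324 features to the dense head; stacked is the default because
    the extra spatial contraction of ``spatial`` attenuates patch-level
    signal enough to visibly slow learning (see docs/methods.md).
    """
    v = fm.values
    if v.min() < 0.0 or v.max() > 1.0:
        raise ValueError("layer-2 input must be rescaled to [0, 1]")
    if mode == "spatial":
        h, w, c = v.shape
        if h < KERNEL_SIZE or w < KERNEL_SIZE:
            raise ValueError("spatial mode needs height/width >= 3")
        h_out = (h - KERNEL_SIZE) // STRIDE + 1
        w_out = (w - KERNEL_SIZE) // STRIDE + 1
        all_patches = []
        for ch in range(c):
            patches, _, _ = _extract_patches(v[:, :, ch])
            all_patches.append(patches)
        z, _ = quanvolve_batch(np.concatenate(all_patches, axis=0), params2.theta)
        # (c, h_out*w_out, 9) -> (h_out, w_out, c*9)
        z = z.reshape(c, h_out * w_out, N_QUBITS)
        out = np.transpose(z, (1, 0, 2)).reshape(h_out, w_out, c * N_QUBITS)
        return FeatureMap(out)
    if mode == "stacked":
        h, w, c = v.shape
        if c != N_QUBITS:
            raise ValueError("stacked mode needs exactly 9 input channels")
        z, _ = quanvolve_batch(v.reshape(h * w, c), params2.theta)
        return FeatureMap(z.reshape(h, w, N_QUBITS))
    raise ValueError(f"unknown layer-2 mode: {mode!r}")


# ---------------------------------------------------------------------------
# Batched fast path.  All patches share the kernel unitary, so the 80 kernel
# gates are applied once to a (B, 512) block of statevectors.


def _kernel_gate_list(theta: np.ndarray) -> list:
    """[(matrix, wires, [(slot, dmatrix), ...]), ...] for the 80 kernel gates."""
    theta = np.asarray(theta, dtype=float).ravel()
    gates = []
    for pair in range(N_QUBITS - 1):
        qubit = {"a": pair, "b": pair + 1}
        for name, wires, slots in _BLOCK:
            if name == "CNOT":
                gates.append((gate_matrix("CNOT"),
                              (qubit[wires[0]], qubit[wires[1]]), []))
            else:
                angles = tuple(theta[s] for s in slots)
                derivs = [(s, gate_matrix_deriv(name, angles, pos))
                          for pos, s in enumerate(slots)]
                gates.append((gate_matrix(name, angles), (qubit[wires],), derivs))
    return gates


def _encode_states(patches: np.ndarray) -> np.ndarray:
    """Product states RX(p*pi/2)|0> per qubit for a (B, 9) pixel block."""
    ang = patches * (np.pi / 2)
    c = np.cos(ang / 2)
    s = np.sin(ang / 2)
    state = np.ones((patches.shape[0], 1), dtype=complex)
    for q in range(N_QUBITS):
        factor = np.stack([c[:, q], -1j * s[:, q]], axis=1)  # RX(a)|0>
        state = (state[:, :, None] * factor[:, None, :]).reshape(state.shape[0], -1)
    return state


def quanvolve_batch(patches: np.ndarray, theta: np.ndarray,
                    keep_tape: bool = False):
    """Run the shared kernel on a (B, 9) block of patches at once.

    Returns ``(z, tape)`` with ``z`` of shape (B, 9) — the Pauli-Z
    expectations per patch — and ``tape`` (if requested) holding the
    intermediate states needed by :func:`quanvolve_batch_backward`.
    """
    patches = np.asarray(patches, dtype=float)
    if patches.ndim != 2 or patches.shape[1] != N_QUBITS:
        raise ValueError("patches must have shape (B, 9)")
    gates = _kernel_gate_list(theta)
    psi = _encode_states(patches)
    for mat, wires, _ in gates:
        psi = apply_unitary(psi, mat, wires, N_QUBITS)
    z = (np.abs(psi) ** 2) @ _ZSIGNS.T
    # only the final state is kept: the adjoint sweep uncomputes the rest
    tape = (patches, gates, psi) if keep_tape else None
    return z, tape


def quanvolve_batch_backward(tape, z_grads: np.ndarray,
                             need_input_grads: bool = False):
    """Reverse-mode sweep for :func:`quanvolve_batch`.

    ``z_grads`` is (B, 9) — dL/dz per patch and wire.  Returns
    ``(theta_grads, input_grads)`` where ``theta_grads`` has length 15
    (summed over the batch and the 8 shared blocks) and ``input_grads``
    is (B, 9) — dL/d(pixel value) — or None.

    Memory stays O(B * 512): intermediate states are uncomputed by
    applying gate adjoints rather than stored during the forward pass.
    """
    patches, gates, psi = tape
    # dL/d(psi*) = sum_w z_grads[:, w] * diag(Z_w) * psi
    lam = ((z_grads @ _ZSIGNS) * psi).astype(complex)
    theta_grads = np.zeros(N_KERNEL_PARAMS)
    for j in range(len(gates) - 1, -1, -1):
        mat, wires, derivs = gates[j]
        psi = apply_unitary(psi, mat.conj().T, wires, N_QUBITS)  # uncompute
        for slot, dmat in derivs:
            dpsi = apply_unitary(psi, dmat, wires, N_QUBITS)
            theta_grads[slot] += 2.0 * float(
                np.real(np.sum(np.conj(lam) * dpsi)))
        lam = apply_unitary(lam, mat.conj().T, wires, N_QUBITS)

    input_grads = None
    if need_input_grads:
        # d(psi0)/d(angle_q) = -i/2 X_q psi0; pixel -> angle is * pi/2
        psi0 = psi
        input_grads = np.empty_like(patches)
        xhalf = np.array([[0, -0.5j], [-0.5j, 0]])
        for q in range(N_QUBITS):
            dpsi = apply_unitary(psi0, xhalf, (q,), N_QUBITS)
            input_grads[:, q] = 2.0 * np.real(
                np.sum(np.conj(lam) * dpsi, axis=1)) * (np.pi / 2)
    return theta_grads, input_grads
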