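import numpy as np
import pytest

from quanvnet import datasets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_small():
    """A small balanced synthetic set shared across tests (28x28)."""
    cfg = datasets.SynthConfig(n_images=40, class_balance=0.5, seed=99)
    return datasets.generate_synthetic(cfg)


@pytest.fixture(scope="session")
def synth_small_14(synth_small):
    """The same set preprocessed to 14x14 in [0,1]."""
    imgs = np.clip(datasets.normalize(datasets.downsample_2x(synth_small.images)),
                   0.0, 1.0)
    return datasets.LabeledImageSet(imgs, synth_small.labels, "train")


def dense_unitary(op_mat, wires, n):
    """Embed a 1- or 2-qubit gate into the full 2^n x 2^n unitary by
    explicit Kronecker products (brute-force oracle, independent of the
    simulator's tensor-contraction path).  Qubit 0 is the most
    significant bit, so the wire-w factor sits w-th in the kron chain.

    The gate is expanded as a sum over matrix units: op = sum
    op[r, c] |r><c| with r, c split bitwise over the wires.
    """
    from functools import reduce

    unit = [[np.zeros((2, 2)) for _ in range(2)] for _ in range(2)]
    for a in range(2):
        for b in range(2):
            unit[a][b][a, b] = 1.0
    k = len(wires)
    dim = 2**n
    full = np.zeros((dim, dim), dtype=complex)
    for row in range(2**k):
        for col in range(2**k):
            coeff = op_mat[row, col]
            if coeff == 0:
                continue
            factors = [np.eye(2)] * n
            for pos, w in enumerate(wires):
                rbit = (row >> (k - 1 - pos)) & 1
                cbit = (col >> (k - 1 - pos)) & 1
                factors[w] = unit[rbit][cbit]
            full += coeff * reduce(np.kron, factors)
    return full
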