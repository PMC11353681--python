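"""Hybrid quanvolutional classifier, its training loop, and the
architecture-matched classical CNN baseline.

The quantum model: a 14x14 image in [0,1] passes through two
quanvolution layers (shared 15-parameter kernels, 3x3, stride 2), the
layer-1 expectations are rescaled from [−1,1] to [0,1] before
re-encoding, the final feature map is flattened (row-major,
channel-last) into 324 features, and a single dense layer produces a raw
logit.  Loss is binary cross-entropy with logits; sigmoid(logit) > 0.5
means positive (normal/benign), a tie at exactly 0.5 is classified
malignant.  Trainable parameters: 15 + 15 quantum angles + 324 weights
+ 1 bias = 355.

The classical twin mirrors the shape arithmetic: two 3x3 stride-2
convolutions with 9 channels each (the second grouped per channel, as
the spatial quantum layer treats each channel independently), tanh
activations standing in for the [−1,1] expectation range, then the same
flatten + dense head.

Optimization is plain Adam (b1=0.9, b2=0.999, eps=1e-8) with L2 weight
decay folded into the gradient of every parameter, quantum angles
included.  All randomness flows from the config seed, so two runs with
the same seed produce bitwise-identical histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import quanv_core as qc
from .quanv_core import KernelParams, N_KERNEL_PARAMS, N_QUBITS

__all__ = [
    "ModelParams",
    "CnnParams",
    "TrainConfig",
    "TrainHistory",
    "forward",
    "forward_batch",
    "bce_with_logits",
    "predict",
    "train",
    "baseline_cnn_forward",
    "param_count",
    "init_model",
    "init_cnn",
    "save_checkpoint",
    "load_checkpoint",
]

N_FEATURES = 324  # 2*2*81 spatial mode == 6*6*9 stacked mode


@dataclass
class ModelParams:
    """All trainable parameters of the hybrid model."""

    kernel1: KernelParams
    kernel2: KernelParams
    fc_weights: np.ndarray  # (324,)
    fc_bias: float

    def __post_init__(self):
        w = np.asarray(self.fc_weights, dtype=float).ravel()
        if w.size != N_FEATURES:
            raise ValueError(f"dense head expects {N_FEATURES} inputs, got {w.size}")
        self.fc_weights = w
        self.fc_bias = float(self.fc_bias)


@dataclass
class CnnParams:
    """Classical baseline: two 3x3 stride-2 convolutions + dense head."""

    conv1_w: np.ndarray  # (9, 3, 3), 1 input channel
    conv1_b: np.ndarray  # (9,)
    conv2_w: np.ndarray  # (9, 3, 3), grouped: one filter per channel
    conv2_b: np.ndarray  # (9,)
    fc_weights: np.ndarray  # (36,)
    fc_bias: float


@dataclass
class TrainConfig:
    learning_rate: float = 1e-2
    weight_decay: float = 1e-5
    batch_size: int = 10
    epochs: int = 15
    seed: int = 0
    layer2_mode: str = "stacked"
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be nonnegative")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.layer2_mode not in ("spatial", "stacked"):
            raise ValueError(f"unknown layer2_mode {self.layer2_mode!r}")


@dataclass
class TrainHistory:
    """One record per epoch."""

    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)

    def append(self, tl, ta, vl, va):
        self.train_loss.append(float(tl))
        self.train_acc.append(float(ta))
        self.val_loss.append(float(vl))
        self.val_acc.append(float(va))

    def json_lines(self) -> str:
        out = []
        for e in range(len(self.train_loss)):
            out.append(json.dumps({
                "epoch": e + 1,
                "train_loss": self.train_loss[e],
                "train_acc": self.train_acc[e],
                "val_loss": self.val_loss[e],
                "val_acc": self.val_acc[e],
            }))
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Losses and decisions.


def bce_with_logits(logit, label) -> float:
    """Numerically stable binary cross-entropy on a raw logit.

    ``max(z,0) - z*y + log(1 + exp(-|z|))`` — never exponentiates a
    positive number.
    """
    z = float(logit)
    y = float(label)
    if y not in (0.0, 1.0):
        raise ValueError("label must be 0 or 1")
    return max(z, 0.0) - z * y + np.log1p(np.exp(-abs(z)))


def _sigmoid(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict(logit, threshold: float = 0.5) -> int:
    """1 (normal/benign) iff sigmoid(logit) strictly exceeds the threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return int(_sigmoid(np.asarray(logit, dtype=float)) > threshold) \
        if np.ndim(logit) == 0 else (_sigmoid(logit) > threshold).astype(int)


# ---------------------------------------------------------------------------
# Quantum model forward/backward.  Everything is batched over images: the
# 36 layer-1 windows of every image in the minibatch are simulated as one
# (B*36, 512) statevector block.


def _layer_geometry(h, w):
    return (h - 3) // 2 + 1, (w - 3) // 2 + 1


def _extract_batch_patches(images: np.ndarray):
    """(B, H, W) -> (B * h_out * w_out, 9) row-major windows."""
    b, h, w = images.shape
    h_out, w_out = _layer_geometry(h, w)
    patches = np.empty((b, h_out, w_out, 9))
    for r in range(h_out):
        for c in range(w_out):
            patches[:, r, c] = images[:, 2 * r:2 * r + 3,
                                      2 * c:2 * c + 3].reshape(b, 9)
    return patches.reshape(-1, 9), h_out, w_out


def _scatter_batch_patches(grads: np.ndarray, b, h, w):
    """Adjoint of :func:`_extract_batch_patches` (overlaps accumulate)."""
    h_out, w_out = _layer_geometry(h, w)
    g = grads.reshape(b, h_out, w_out, 3, 3)
    out = np.zeros((b, h, w))
    for r in range(h_out):
        for c in range(w_out):
            out[:, 2 * r:2 * r + 3, 2 * c:2 * c + 3] += g[:, r, c]
    return out


def forward_batch(images: np.ndarray, model: ModelParams,
                  mode: str = "stacked", keep_tape: bool = False):
    """Logits for a (B, 14, 14) image batch; optionally keep the autodiff tape."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    b, h, w = images.shape
    # layer 1
    p1, h1, w1 = _extract_batch_patches(images)
    z1, tape1 = qc.quanvolve_batch(p1, model.kernel1.theta, keep_tape=keep_tape)
    r1 = (z1 + 1.0) / 2.0  # rescale to [0,1]
    fm1 = r1.reshape(b, h1, w1, N_QUBITS)
    # layer 2
    if mode == "spatial":
        h2, w2 = _layer_geometry(h1, w1)
        # per image and channel, extract stride-2 windows of the 6x6 plane
        planes = np.transpose(fm1, (0, 3, 1, 2)).reshape(b * N_QUBITS, h1, w1)
        p2, _, _ = _extract_batch_patches(planes)
        z2, tape2 = qc.quanvolve_batch(p2, model.kernel2.theta, keep_tape=keep_tape)
        # (b, 9ch, h2*w2, 9wire) -> (b, h2, w2, 81)
        z2r = z2.reshape(b, N_QUBITS, h2 * w2, N_QUBITS)
        feats = np.transpose(z2r, (0, 2, 1, 3)).reshape(b, h2, w2,
                                                        N_QUBITS * N_QUBITS)
    elif mode == "stacked":
        p2 = fm1.reshape(b * h1 * w1, N_QUBITS)
        z2, tape2 = qc.quanvolve_batch(p2, model.kernel2.theta, keep_tape=keep_tape)
        feats = z2.reshape(b, h1, w1, N_QUBITS)
    else:
        raise ValueError(f"unknown layer-2 mode: {mode!r}")
    flat = feats.reshape(b, -1)
    if flat.shape[1] != model.fc_weights.size:
        raise ValueError(
            f"flattened features {flat.shape[1]} do not match dense head "
            f"{model.fc_weights.size}")
    logits = flat @ model.fc_weights + model.fc_bias
    if not keep_tape:
        return logits, None
    tape = {"images_shape": (b, h, w), "mode": mode, "tape1": tape1,
            "tape2": tape2, "flat": flat, "fm1_shape": fm1.shape}
    return logits, tape


def forward(image, model: ModelParams, mode: str = "stacked") -> float:
    """Raw logit for a single image (no sigmoid — the loss takes logits)."""
    logits, _ = forward_batch(np.asarray(image, dtype=float)[None], model, mode)
    return float(logits[0])


def backward_batch(tape, dlogits: np.ndarray, model: ModelParams):
    """Gradients of sum_i dlogits[i] * logit_i w.r.t. all model parameters."""
    b, h, w = tape["images_shape"]
    mode = tape["mode"]
    flat = tape["flat"]
    g_w = dlogits @ flat  # (324,)
    g_b = float(np.sum(dlogits))
    dflat = np.outer(dlogits, model.fc_weights)  # (b, 324)
    bh, bw, _ = tape["fm1_shape"][1], tape["fm1_shape"][2], None
    h1, w1 = bh, bw
    if mode == "spatial":
        h2, w2 = _layer_geometry(h1, w1)
        dfeats = dflat.reshape(b, h2, w2, N_QUBITS, N_QUBITS)
        dz2 = np.transpose(dfeats, (0, 3, 1, 2, 4)).reshape(-1, N_QUBITS)
        g_theta2, dinp2 = qc.quanvolve_batch_backward(
            tape["tape2"], dz2, need_input_grads=True)
        dplanes = _scatter_batch_patches(dinp2, b * N_QUBITS, h1, w1)
        dfm1 = np.transpose(dplanes.reshape(b, N_QUBITS, h1, w1), (0, 2, 3, 1))
    else:  # stacked
        dz2 = dflat.reshape(-1, N_QUBITS)
        g_theta2, dinp2 = qc.quanvolve_batch_backward(
            tape["tape2"], dz2, need_input_grads=True)
        dfm1 = dinp2.reshape(b, h1, w1, N_QUBITS)
    # rescale r = (z+1)/2 -> dz = dr/2
    dz1 = (dfm1 / 2.0).reshape(-1, N_QUBITS)
    g_theta1, _ = qc.quanvolve_batch_backward(tape["tape1"], dz1)
    return {"kernel1": g_theta1, "kernel2": g_theta2,
            "fc_weights": g_w, "fc_bias": g_b}


# ---------------------------------------------------------------------------
# Classical baseline.


def init_model(rng: np.random.Generator) -> ModelParams:
    """Quantum angles ~ U[0, 2pi); dense weights ~ U[-1/sqrt(324), 1/sqrt(324)]."""
    k1 = KernelParams(rng.uniform(0.0, 2 * np.pi, N_KERNEL_PARAMS))
    k2 = KernelParams(rng.uniform(0.0, 2 * np.pi, N_KERNEL_PARAMS))
    bound = 1.0 / np.sqrt(N_FEATURES)
    w = rng.uniform(-bound, bound, N_FEATURES)
    bias = float(rng.uniform(-bound, bound))
    return ModelParams(k1, k2, w, bias)


def init_cnn(rng: np.random.Generator) -> CnnParams:
    b1 = 1.0 / 3.0  # fan-in 9
    conv1_w = rng.uniform(-b1, b1, (9, 3, 3))
    conv1_b = rng.uniform(-b1, b1, 9)
    conv2_w = rng.uniform(-b1, b1, (9, 3, 3))
    conv2_b = rng.uniform(-b1, b1, 9)
    b2 = 1.0 / 6.0  # fan-in 36
    w = rng.uniform(-b2, b2, 36)
    bias = float(rng.uniform(-b2, b2))
    return CnnParams(conv1_w, conv1_b, conv2_w, conv2_b, w, bias)


def _conv_windows(x: np.ndarray):
    """(B, H, W, C) -> (B, h_out, w_out, 3, 3, C) stride-2 windows."""
    b, h, w, c = x.shape
    h_out, w_out = _layer_geometry(h, w)
    out = np.empty((b, h_out, w_out, 3, 3, c))
    for r in range(h_out):
        for s in range(w_out):
            out[:, r, s] = x[:, 2 * r:2 * r + 3, 2 * s:2 * s + 3]
    return out


def baseline_cnn_forward(images, params: CnnParams, keep_tape: bool = False):
    """Logits of the classical twin for a (B, 14, 14) batch.

    conv1: 1->9 channels, 3x3 stride 2, tanh -> (B, 6, 6, 9);
    conv2: grouped per channel, 3x3 stride 2, tanh -> (B, 2, 2, 9);
    flatten -> dense -> logit.
    """
    x = np.asarray(images, dtype=float)
    if x.ndim == 2:
        x = x[None]
    b = x.shape[0]
    win1 = _conv_windows(x[..., None])[..., 0]  # (B, 6, 6, 3, 3)
    pre1 = np.einsum("brsxy,cxy->brsc", win1, params.conv1_w) + params.conv1_b
    a1 = np.tanh(pre1)  # (B, 6, 6, 9)
    win2 = _conv_windows(a1)  # (B, 2, 2, 3, 3, 9)
    pre2 = np.einsum("brsxyc,cxy->brsc", win2, params.conv2_w) + params.conv2_b
    a2 = np.tanh(pre2)  # (B, 2, 2, 9)
    flat = a2.reshape(b, -1)
    logits = flat @ params.fc_weights + params.fc_bias
    if not keep_tape:
        return logits, None
    return logits, {"x": x, "win1": win1, "a1": a1, "win2": win2, "a2": a2,
                    "flat": flat}


def baseline_cnn_backward(tape, dlogits: np.ndarray, params: CnnParams):
    flat, a1, a2 = tape["flat"], tape["a1"], tape["a2"]
    b = flat.shape[0]
    g_w = dlogits @ flat
    g_b = float(np.sum(dlogits))
    dflat = np.outer(dlogits, params.fc_weights)
    da2 = dflat.reshape(a2.shape)
    dpre2 = da2 * (1.0 - a2**2)
    g_c2w = np.einsum("brsc,brsxyc->cxy", dpre2, tape["win2"])
    g_c2b = np.einsum("brsc->c", dpre2)
    # scatter dpre2 * conv2_w back onto a1
    da1 = np.zeros_like(a1)
    h2, w2 = a2.shape[1], a2.shape[2]
    contrib = np.einsum("brsc,cxy->brsxyc", dpre2, params.conv2_w)
    for r in range(h2):
        for s in range(w2):
            da1[:, 2 * r:2 * r + 3, 2 * s:2 * s + 3, :] += contrib[:, r, s]
    dpre1 = da1 * (1.0 - a1**2)
    g_c1w = np.einsum("brsc,brsxy->cxy", dpre1, tape["win1"])
    g_c1b = np.einsum("brsc->c", dpre1)
    return {"conv1_w": g_c1w, "conv1_b": g_c1b, "conv2_w": g_c2w,
            "conv2_b": g_c2b, "fc_weights": g_w, "fc_bias": g_b}


# ---------------------------------------------------------------------------
# Optimizer and training loop.


class Adam:
    """Classic Adam with L2 weight decay folded into the gradient."""

    def __init__(self, shapes: dict, lr: float, weight_decay: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, b1, b2, eps
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = np.asarray(grads[k], dtype=float) + self.wd * np.asarray(p)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out[k] = np.asarray(p) - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def _model_to_dict(model: ModelParams) -> dict:
    return {"kernel1": model.kernel1.theta, "kernel2": model.kernel2.theta,
            "fc_weights": model.fc_weights, "fc_bias": np.array(model.fc_bias)}


def _model_from_dict(d: dict) -> ModelParams:
    return ModelParams(KernelParams(d["kernel1"]), KernelParams(d["kernel2"]),
                       d["fc_weights"], float(d["fc_bias"]))


def _cnn_to_dict(p: CnnParams) -> dict:
    return {"conv1_w": p.conv1_w, "conv1_b": p.conv1_b, "conv2_w": p.conv2_w,
            "conv2_b": p.conv2_b, "fc_weights": p.fc_weights,
            "fc_bias": np.array(p.fc_bias)}


def _cnn_from_dict(d: dict) -> CnnParams:
    return CnnParams(d["conv1_w"], d["conv1_b"], d["conv2_w"], d["conv2_b"],
                     d["fc_weights"], float(d["fc_bias"]))


def _eval_split(images, labels, params, kind, mode, threshold):
    if len(images) == 0:
        return float("nan"), float("nan")
    if kind == "quantum":
        logits, _ = forward_batch(images, params, mode)
    else:
        logits, _ = baseline_cnn_forward(images, params)
    losses = [bce_with_logits(z, y) for z, y in zip(logits, labels)]
    preds = (_sigmoid(logits) > threshold).astype(int)
    return float(np.mean(losses)), float(np.mean(preds == labels))


def train(train_set, val_set, config: TrainConfig, kind: str = "quantum",
          callback=None):
    """Minibatch Adam training; returns (params, TrainHistory).

    ``train_set``/``val_set`` carry ``.images`` (N, 14, 14) in [0,1] and
    binary ``.labels``.  Fully reproducible given ``config.seed``.
    """
    images = np.asarray(train_set.images, dtype=float)
    labels = np.asarray(train_set.labels, dtype=int)
    if images.size == 0:
        raise ValueError("empty training split")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary")
    vimages = np.asarray(val_set.images, dtype=float) if val_set is not None \
        else np.empty((0,) + images.shape[1:])
    vlabels = np.asarray(val_set.labels, dtype=int) if val_set is not None \
        else np.empty(0, dtype=int)

    rng = np.random.default_rng(config.seed)
    if kind == "quantum":
        params = init_model(rng)
        pdict = _model_to_dict(params)
    elif kind == "classical":
        params = init_cnn(rng)
        pdict = _cnn_to_dict(params)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    opt = Adam({k: v.shape for k, v in pdict.items()},
               config.learning_rate, config.weight_decay)
    history = TrainHistory()
    n = len(images)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = images[idx], labels[idx]
            if kind == "quantum":
                model = _model_from_dict(pdict)
                logits, tape = forward_batch(xb, model, config.layer2_mode,
                                             keep_tape=True)
                dlogits = (_sigmoid(logits) - yb) / len(idx)
                grads = backward_batch(tape, dlogits, model)
            else:
                cnn = _cnn_from_dict(pdict)
                logits, tape = baseline_cnn_forward(xb, cnn, keep_tape=True)
                dlogits = (_sigmoid(logits) - yb) / len(idx)
                grads = baseline_cnn_backward(tape, dlogits, cnn)
            pdict = opt.step(pdict, grads)
        cur = _model_from_dict(pdict) if kind == "quantum" else _cnn_from_dict(pdict)
        tl, ta = _eval_split(images, labels, cur, kind,
                             config.layer2_mode, config.threshold)
        vl, va = _eval_split(vimages, vlabels, cur, kind,
                             config.layer2_mode, config.threshold)
        history.append(tl, ta, vl, va)
        if callback is not None:
            callback(epoch + 1, history)
    final = _model_from_dict(pdict) if kind == "quantum" else _cnn_from_dict(pdict)
    return final, history


def param_count(kind: str = "quantum", mode: str = "stacked") -> dict:
    """Trainable-parameter audit."""
    if kind == "quantum":
        extractor = 2 * N_KERNEL_PARAMS
        head = N_FEATURES + 1
        return {"extractor": extractor, "head": head,
                "total": extractor + head}
    if kind == "classical":
        extractor = (9 * 9 + 9) + (9 * 9 + 9)
        head = 36 + 1
        return {"extractor": extractor, "head": head,
                "total": extractor + head}
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# Checkpoints: flat key -> array container.


def save_checkpoint(path, params, config: TrainConfig, kind: str) -> None:
    if kind == "quantum":
        d = _model_to_dict(params)
    else:
        d = _cnn_to_dict(params)
    meta = json.dumps({
        "kind": kind,
        "learning_rate": config.learning_rate,
        "weight_decay": config.weight_decay,
        "batch_size": config.batch_size,
        "epochs": config.epochs,
        "seed": config.seed,
        "layer2_mode": config.layer2_mode,
        "threshold": config.threshold,
    })
    np.savez(path, __meta__=np.array(meta), **d)


def load_checkpoint(path):
    """Returns (params, TrainConfig, kind)."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        d = {k: data[k] for k in data.files if k != "__meta__"}
    kind = meta.pop("kind")
    config = TrainConfig(**meta)
    params = _model_from_dict(d) if kind == "quantum" else _cnn_from_dict(d)
    return params, config, kind
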