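# Methods

## Problem and model

`quanvnet` classifies small grayscale breast-ultrasound frames as
positive (normal/benign, label 1) or negative (malignant, label 0) with
a *quanvolutional* neural network: a convolutional network whose two
feature-extraction layers are 9-qubit parameterized quantum circuits,
simulated exactly on a classical statevector backend, followed by a
single classical dense layer.

One quanvolution step works on a 3×3 patch of pixels `p ∈ [0,1]⁹`:

1. **Angle embedding.** Qubit *i* (row-major pixel order) is rotated
   from |0⟩ by `RX(p_i · π/2)`, mapping the pixel range onto rotation
   angles in `[0, π/2]`.  On its own this gives `⟨Z_i⟩ = cos(p_i·π/2)`.
2. **Entangling kernel.** A fixed-topology circuit applies one
   SU(4)-style block to every adjacent qubit pair (0,1), (1,2), …,
   (7,8).  Each block is the standard three-CNOT decomposition of an
   arbitrary two-qubit unitary — `U3⊗U3 · CNOT · (RZ⊗RY) · CNOT ·
   (I⊗RY) · CNOT · U3⊗U3` — and **all eight blocks share the same 15
   angles θ**, so one kernel has exactly 15 trainable parameters
   (80 gates total).
3. **Measurement.** The nine Pauli-Z expectations `⟨Z_0⟩ … ⟨Z_8⟩ ∈
   [−1,1]` become the nine channels of one output pixel.

Sliding this over a 14×14 image with stride 2 and no padding yields a
6×6×9 feature map.  The map is rescaled to `[0,1]` via `v ↦ (v+1)/2`
and passed to a second 15-parameter kernel; the result is flattened
(row-major, channel-last) into 324 features and a dense layer
`w·x + b` produces a raw logit.  `sigmoid(logit) > 0.5` means positive;
a tie at exactly 0.5 is classified malignant (the decision rule is
strict).  Trainable parameters: 15 + 15 + 324 + 1 = 355.

## Second-layer composition: `stacked` vs `spatial`

Two readings of "feed the first layer's output into another circuit"
are implemented:

- **stacked** (default): the 9 rescaled channel values at each of the
  36 spatial cells are re-embedded as one 9-qubit register and passed
  through the second kernel, keeping the 6×6×9 shape.
- **spatial**: each channel is treated as a 6×6 image and quanvolved
  again (3×3, stride 2), giving 2×2×81.

Both produce 324 features.  `stacked` is the default on empirical
grounds: the extra spatial contraction of `spatial` attenuates
patch-level signal severely (the standard deviation of the flattened
features drops to ~0.01, and a logistic probe on frozen random-kernel
features plateaus near 86–88% at practical regularization), so within
the short published training budget the spatial composition does not
reliably learn even a cleanly separable task (peak training accuracy
76–84% across seeds on the synthetic benchmark below), while the
stacked composition does (92–95%).  The spatial mode remains fully
supported through `--layer2 spatial` / `layer2_mode="spatial"`.

## Simulation and gradients

States are exact complex-double vectors of length 2⁹ = 512; **qubit 0
is the most significant bit** of the basis index.  Gates act by tensor
contraction on their wires; unitarity is enforced to 1e-12 and norm
conservation to 1e-10 in the tests, with a dense Kronecker-product
matrix oracle as the independent reference.  There is no shot noise, no
mixed states, and no noise model — the model of an ideal simulator.
Global phase is not normalized away; every observable used is
phase-invariant.

Two gradient routes exist and are cross-checked:

- `grad_param_shift`: the parameter-shift rule
  `f'(a) = [f(a+π/2) − f(a−π/2)]/2` per angle position, summed over the
  positions sharing a slot.  Valid for RX/RY/RZ and each U3 angle
  separately (each enters as a single-frequency sinusoid).
- reverse-mode differentiation through the statevector (used by the
  trainer): one forward pass plus one adjoint sweep per circuit, with
  intermediate states *uncomputed* by gate adjoints rather than stored,
  so memory stays O(batch · 512).  All patches of a minibatch are
  simulated as one (B·36, 512) block, which is why training runs in
  minutes rather than days.

Agreement between the two routes is at 1e-10; agreement with central
finite differences (h = 1e-6) at 1e-5/1e-6 is asserted in the suite.

## Training

Binary cross-entropy with logits (stable `max(z,0) − zy +
log(1+e^{−|z|})` form), Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with
learning rate 1e-2, L2 weight decay 1e-5 folded into every parameter's
gradient (quantum angles included), batch size 10, 15 epochs by
default.  Initialization: quantum angles ~ U[0, 2π), dense weights and
bias ~ U[−1/√324, 1/√324], all drawn from the run seed; per-epoch
shuffling comes from the same generator, so one seed fixes the entire
history bitwise.  Epoch metrics are loss/accuracy over the *full*
training and validation splits at epoch end, not running batch
averages.  The trainer records every epoch; no early stopping, no
schedules, no augmentation.

The classical baseline mirrors the shape arithmetic: conv(1→9, 3×3,
stride 2, bias) → tanh → grouped conv(9→9, one 3×3 filter per channel,
stride 2, bias) → tanh → flatten(36) → dense.  tanh stands in for the
[−1,1] expectation range; the grouped second convolution mirrors the
channel-independent quantum second layer.  217 parameters.

## Data

**Real path.** A MedMNIST-layout `.npz` (six arrays
`{train,val,test}_{images,labels}`) is read directly; uint8 images are
scaled to [0,1] and labels binarized with class index 0 = malignant →
0, everything else → 1.  Split sizes are preserved as shipped; a
780-image archive at 7:1:2 carries 546/78/156 images.  Preprocessing
follows the published recipe: 28×28 → 14×14 by non-overlapping 2×2
mean pooling (a deterministic choice; only the target size is
prescribed), global min-max normalization to [0,1], and a nearly
balanced training subset (all minority-class items plus an equal-count
seeded sample of the majority class).

**Synthetic path.** Because the archive is an external download, the
package ships a phantom generator that emulates the gross statistics of
low-resolution breast ultrasound: a mid-gray field under multiplicative
speckle (exponential intensity ≈ squared-Rayleigh amplitudes, scale
0.35), with one hypoechoic (dark) lesion per frame.  Benign lesions are
smooth ellipses (r₀ ~ U(0.18, 0.30)·size, aspect U(0.6, 1)) with a
Gaussian-blurred margin (σ = 1.2 px); malignant lesions are star-convex
polygons `r(φ) = r₀(1 + 0.4·sin(kφ + φ₀))`, k ∈ {5…9}, with a sharper
margin (σ = 0.4 px), a darker core (0.10 vs 0.18 background-relative
level) and a mild posterior acoustic shadow — spiculation, hypoechoic
core and shadowing being classic sonographic malignancy features.
Default prevalence is 73% positive, mirroring the published test-split
ratio (114/156).  The generator is bitwise deterministic per config.

What the phantom does *not* emulate: real anatomy, depth-dependent
attenuation and gain, probe artifacts, lesion texture heterogeneity, or
inter-patient variability.  A green learning test on the phantom
therefore establishes that the pipeline can extract and learn
shape/intensity cues end-to-end — not that it reaches any particular
accuracy on clinical data.  Separability is itself asserted by test:
two hand-crafted features (lesion area fraction and radial roughness of
the segmented mask) support >90% accuracy with a logistic regression,
and the malignant class has strictly higher mean roughness at
irregularity 0.4.

## Metrics

2×2 confusion matrix (rows = truth, columns = prediction), per-class
precision/recall/F1/support, accuracy, macro and support-weighted
averages, and one-vs-rest TPR/FPR with `FPR_k = FP_k/(n − support_k)`.
Zero denominators yield 0 with a warning flag.  In the binary case the
support-weighted recall equals accuracy exactly; the suite asserts the
identity.  Values are stored at full precision and rounded only for
display (2 decimals, half away from zero).  Published reports sometimes
print FPR under other conventions; this package does not attempt to
match any specific printed FPR row and documents its own convention
instead.  `reconstruct_confusion(recalls, supports)` rebuilds counts
from a printed report's recall and support columns via
`TP_k = round(recall_k·support_k)`.

## Numerical choices and degenerate inputs

- Tolerances: unitarity 1e-12, dense-oracle equivalence and norm
  conservation 1e-10, gradient-vs-finite-difference 1e-6 (circuit
  level) and 1e-5 (model level).
- Patch/pixel validation is strict: values outside [0,1] are rejected,
  as are images smaller than the 3×3 kernel and odd-sized inputs to the
  2× downsampler.
- A constant image stack min-max-normalizes to all zeros.
- `balanced_subset` requires both classes; single-class input is an
  error, not a silent pass-through.
- The decision threshold tie (sigmoid exactly 0.5) goes to the
  malignant class.

## Known limitations

- Statevector simulation is exact but exponential in qubit count; the
  engine is capped at 12 qubits and tuned for the 9-qubit kernel.
- The kernel topology is a fixed linear ladder of qubit pairs; no
  all-to-all or random entanglement layouts.
- Single-channel (grayscale) images only; binary classification only.
- The optimizer is plain Adam; no schedules, restarts or gradient
  clipping, so short runs at lr 1e-2 can oscillate near convergence —
  the per-epoch history is recorded precisely so users can pick the
  best epoch.
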