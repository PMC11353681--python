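# quanvnet

Quanvolutional neural networks for binary breast-ultrasound lesion
classification — quantum circuits acting as 3×3 convolutional kernels,
simulated exactly on a classical statevector backend, trained end-to-end
with a classical dense head, and benchmarked against an
architecture-matched classical CNN.

The package is aimed at quantum-machine-learning researchers and
medical-imaging practitioners who want a dependency-light, fully
reproducible reference implementation: the simulator, analytic
gradients, optimizer and training loop are pure numpy, and a synthetic
ultrasound phantom generator means everything — including the tests —
runs offline with no dataset download.

## The model

A 3×3 patch of pixels `p ∈ [0,1]⁹` is angle-embedded onto 9 qubits,
one `RX(p_i · π/2)` rotation per pixel, so the pixel range maps to
rotation angles in `[0, π/2]`.  The embedded register then passes
through a strongly entangling kernel circuit: one SU(4)-style two-qubit
block — `U3⊗U3 → CNOT → RZ⊗RY → CNOT → I⊗RY → CNOT → U3⊗U3` — on each
adjacent qubit pair (0,1)…(7,8), with **all eight blocks sharing the
same 15 angles θ**.  Measuring `⟨Z_w⟩ ∈ [−1,1]` on each wire yields the
nine channels of one output pixel:

    x ∈ [0,1]⁹  →  |ψ⟩ = W(θ) · S(x) |0⟩⊗⁹  →  z_w = ⟨ψ| Z_w |ψ⟩

Sliding the kernel over a 14×14 image (stride 2, no padding) gives a
6×6×9 feature map; a second shared 15-parameter kernel re-encodes it;
the 324 flattened features feed one dense layer producing a logit.
Training minimizes binary cross-entropy with logits using Adam
(lr 1e-2, weight decay 1e-5, batch 10), with gradients obtained by
reverse-mode differentiation through the statevector (cross-checked
against the parameter-shift rule and finite differences in the test
suite).  `sigmoid(logit) > 0.5` ⇒ positive (normal/benign); otherwise
malignant.  355 trainable parameters in total: 30 quantum angles plus a
325-parameter head.

## Worked example

Train on 120 synthetic phantom images (84/12/24 split at 7:1:2, the
training split balanced to 80 images) and evaluate on the held-out
test split:

```sh
quanvnet train --synthetic 120 --seed 1 --out runs/demo
quanvnet evaluate --checkpoint runs/demo/checkpoint.npz \
                  --synthetic 120 --split test --seed 1
```

The evaluation prints a per-class report (this exact output, since
every source of randomness flows from the seed):

```
                precision   recall  f1-score  support

             0       1.00     0.83      0.91       12
             1       0.86     1.00      0.92       12

      accuracy                          0.92       24
     macro avg       0.93     0.92      0.92       24
  weighted avg       0.93     0.92      0.92       24

           TPR       0.83     1.00
           FPR       0.00     0.17
```

Row `0` is the malignant class, row `1` normal/benign: 10 of 12
malignant lesions are caught (recall 0.83), every benign case is
recognized (recall 1.00), and the two missed malignant lesions are the
benign class's only false positives (FPR 0.17 one-vs-rest).  Overall
accuracy is 92% on this easy, balanced phantom task — the phantom is a
plumbing check, not a clinical benchmark.

Other entry points:

```sh
quanvnet generate --n 80 --seed 3 --out data/       # phantom PNGs + labels.csv
quanvnet param-count                                # {"extractor": 30, "head": 325, "total": 355}
quanvnet describe-circuit --which kernel            # 80 gates, 15 shared slots, as text
quanvnet train --archive breastmnist.npz ...        # real data, if you have the archive
quanvnet train --mode classical-baseline ...        # the matched classical CNN
```

Real-data path: point `--archive` at a MedMNIST-layout `.npz`
(`train/val/test` images + labels); images are scaled to [0,1],
labels binarized (malignant vs normal/benign), 28×28 frames
mean-pooled to 14×14 and min-max normalized, and the training split
balanced, following the published preprocessing.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch: it generates
a fresh synthetic phantom set from the seed, preprocesses it, trains
the quanvolutional classifier with the published hyperparameters,
evaluates the held-out split and prints the classification report to
stderr, writing the (empty) acceptance JSON object to `--out`.
Runtime is a few minutes on one CPU.

See `docs/methods.md` for the full model description, the phantom
generator's assumptions, numerical tolerances and known limitations.
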