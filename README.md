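# subtomocl

Contrastive self-supervised pretraining and semi-supervised fine-tuning for
**cryo-electron tomography subtomogram classification**, with a built-in
synthetic data generator so the whole pipeline runs end to end on one CPU
with no external data.

## The problem

Cryo-ET yields 3D density volumes of frozen-hydrated cells. Classifying the
macromolecule at the centre of a small cubic *subtomogram* is hard: volumes
are heavily corrupted by noise (SNR well below 0.1), by the **missing
wedge** (a double wedge of unmeasured 3D Fourier coefficients caused by the
limited tilt range), and by crowding from neighbouring macromolecules —
while labelled examples are scarce because annotation requires experts.
Contrastive self-supervised learning (CSSL) uses the *unlabelled* volumes to
pretrain an encoder, which is then fine-tuned on whatever labels exist.

## The method

Two augmented views `x_q, x_k` of the same volume are a *positive pair*;
views of different volumes are negatives. A query encoder `f_q` and a
momentum key encoder `f_k` produce unit-norm embeddings `q = f_q(x_q)`,
`k = f_k(x_k)`, and the queue-based contrastive (InfoNCE) loss for a batch
of pairs against a FIFO queue `{k_i}` of K historical keys is

    L = − mean_j log [ exp(q_j·k_j/τ) / ( exp(q_j·k_j/τ) + Σ_i exp(q_j·k_i/τ) ) ]

with temperature τ = 0.2. The query encoder trains by backpropagation
(Adam, lr 1e-4, weight decay 1e-4, batch 16); the key encoder receives no
gradients and tracks it as an exponential running average

    θ_k ← m·θ_k + (1 − m)·θ_q,    m = 0.999,

and each step the fresh keys replace the oldest mini-batch in the queue
(K = 128 by default). A SimCLR-style variant (in-batch negatives, single
encoder) is also provided. The encoder is a residual 3D CNN (3×3×3
convolutions, 2× max pooling, channel-doubling stages, a channel
concatenation of the last two same-shape residual stages, FC-1024 →
embedding/classification heads). Augmentations are cryo-ET-appropriate and
mild: a random resized crop (p = 0.5, volume fraction 0.5–1) and a random
affine (p = 0.5; rotation ±45° about z, in-plane translations ≤ 0.1 of the
side, scale within ±0.1).

Fine-tuning trains the full network with cross-entropy (SGD + cosine decay,
lr 5e-4, 50 epochs, best-validation checkpoint) on 25/50/75/100 % label
fractions, repeats each cell over seeds, and compares methods with a
two-tailed Student t-test. A 3D Grad-CAM is included for qualitative
inspection of what drives a classification.

The synthetic generator emulates simulated cryo-ET benchmarks: parametric
multi-component density motifs per class, random rotations/translations,
2–6 random neighbours outside the central third, an exact missing-wedge
Fourier mask, and additive Gaussian noise calibrated to a target
SNR = Var(signal)/Var(noise) (defaults: 10 classes × 500 volumes of 32³ at
SNR ∞ / 0.05 / 0.03, split 60:20:20).

## Worked example

With a reduced experiment file (tiny encoder; pretrain queue 16, batch 8,
10 epochs; fine-tune 15 epochs — see `tests/` for the exact YAML shape):

```
$ subtomocl simulate --out data --classes 3 --per-class 20 --side 16 \
      --snr 0.5 --wedge 30 --neighbors 1 3 --seed 5
wrote 60 volumes and manifest.csv to data

$ subtomocl pretrain --method moco --manifest data/manifest.csv \
      --config exp.yaml --seed 1 --out pre.npz
moco pretraining: epoch0 loss 2.7245 -> final 2.4609; weights at pre.npz, log at pre.loss.csv
```

The pretraining loss starts near ln(K+1) = 2.83 (a fresh encoder cannot
tell keys apart, so the softmax over 1+K logits is uniform) and falls as
the encoder learns to rank each query's own key above the queue.
Fine-tuning on the labelled fraction and evaluating:

```
$ subtomocl finetune --weights pre.npz --manifest data/manifest.csv \
      --fraction 1.0 --config exp.yaml --seed 2 --out ft.npz
fine-tuned on 36 labelled volumes; best val acc 41.7%
$ subtomocl evaluate --checkpoint ft.npz --manifest data/manifest.csv
test accuracy: 58.3%
```

Chance on three balanced classes is 33.3 %; accuracy on this 12-volume test
split moves in steps of 8.3 %. At study scale the package's benchmark (150
volumes, 3 classes, 16³, SNR 0.5, 20 pretraining epochs, 3 seeds; run via
`scripts/acceptance.py --seed 1`) gives mean test accuracies of 50.0 %
(MoCo init) vs 38.9 % (random init) at 25 % labels and 68.9 % vs 45.6 % at
100 %, with both methods improving as labels are added — the
pretraining-benefit pattern the method is built to deliver.

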