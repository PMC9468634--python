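# Methods

## Scope and model

`subtomocl` implements instance-discrimination contrastive pretraining for
cubic cryo-ET subtomograms, plus the supervised fine-tuning protocol that
measures its benefit under scarce labels. The package contains six layers:
synthetic data generation, volume/manifest I/O, 3D augmentation, a residual
3D CNN encoder, the contrastive training loops, and the downstream
evaluation grid. Everything is numpy: the network layers (im2col 3×3×3
convolutions, 2× max pooling, dense layers, ReLU, L2 normalization, softmax
cross-entropy) carry hand-written backward passes, and Adam / momentum-SGD
optimizers with a cosine schedule drive training. This keeps the whole
pipeline runnable and exactly reproducible on a single CPU; it is not built
for GPU-scale throughput.

## Contrastive objective

For unit embeddings, batch queries `q_j`, positive keys `k_j` and a queue
of `K` historical keys `k_i`, the loss is the softmax cross-entropy over
`1 + K` logits `[q_j·k_j, q_j·k_1, …, q_j·k_K] / τ` with the positive in
class 0 — i.e. the positive similarity appears in the denominator together
with the queue terms. Two exact consequences used as oracles: if all
similarities are equal the loss is `ln(K+1)` for any `τ`; and the gradient
with respect to `q` is `((p₀−1)k_j + Σᵢ pᵢ kᵢ)/(τB)` with `p` the softmax.
Keys are constants (no gradient); the key encoder's parameters are updated
only by `θ_k ← m·θ_k + (1−m)·θ_q` *after* each optimizer step on `θ_q`.
Embeddings are L2-normalized before the dot product: with `τ = 0.2` the
logits span `±5`, which is the regime the temperature is designed for; raw
unnormalized dot products would make `τ` meaningless.

Queue contents are seeded with key-encoder embeddings of augmented training
volumes rather than random unit vectors. Random rows are near-orthogonal to
every real query, which makes the first ~`K/B` steps artificially easy and
puts a spurious dip at the start of the loss log; warm keys start the loss
at its natural `≈ ln(K+1)` level so epoch-over-epoch decrease reflects
learning. A `init_queue` primitive producing random unit rows remains
available.

The SimCLR-style loop uses one encoder for both views; each of the `2B`
views takes the other `2(B−1)` views as negatives and its partner as the
positive, same loss form, no queue or momentum machinery.

## Encoder

The classification network is a residual 3D CNN: stem 3×3×3 convolution
(stride 1, 'same'), then `n_residual_stages` of
`[conv → ReLU → conv] + identity skip → ReLU → 2× max pool → channel-
doubling transition conv` (width capped at 4× the base), then two further
residual stages at constant shape whose outputs are concatenated
channel-wise, then flatten → FC(`fc_width`) → ReLU → two heads: FC(`L`)
with L2 normalization for contrastive training and FC(`n_classes`) with
softmax for classification. There is no batch normalization or dropout:
the reference design names only conv/pool/FC/ReLU/softmax layers, and
omitting stateful normalization makes evaluation-mode determinism and the
momentum parameter copy exact (no running-statistics buffers to
reconcile). He initialization throughout, float32 parameters.

Defaults: 32³ input, 64 base filters, 3 pooled stages, FC-1024, L = 128.
`tiny_mode` (16³, 8 filters, 2 stages, FC-64, L = 32, <10⁶ parameters) is
the desk-scale test surface. Grad-CAM splits the network at the channel
concatenation: the map is `ReLU(Σ_c w_c A_c)` with `w_c` the spatial mean
of the target-logit gradient at the concat activation `A`, trilinearly
upsampled and max-normalized; the head/feature split lets tests validate
the captured gradient by finite differences without touching convolutions.

## Augmentation

Two stochastic operations per view, each behind an independent Bernoulli
gate at p = 0.5: a random resized crop (cubic sub-block covering a volume
fraction uniform in [0.5, 1], cube-root side law, resampled back to full
size) and a single-pass affine resampling composed in the fixed order
scale → rotate-about-z → translate (scale uniform in [0.9, 1.1]; angle
uniform in [−45°, 45°]; x/y translations uniform within ±0.1 of the side;
no z translation). Trilinear interpolation with constant-zero fill;
near-integer transform matrices are snapped so 90° turns and whole-voxel
shifts are bit-exact. Both views are z-scored after augmentation.
Augmentations never see labels, and the pretraining loops accept a
volumes-only container so label blindness is structural. The crop "scale"
is interpreted as a volume fraction (the 3D analogue of area fraction); a
side-fraction mode is available via `crop_mode`.

## Synthetic data

Each class is a fixed union of Gaussian-profiled **spherical shells** on
four radius bands (0.06/0.11/0.16/0.21 of the side) plus two small
off-centre Gaussian blobs. Classes differ in (a) which bands are occupied —
band codes of size 1, 2 or 4 chosen so that no two codes are nested and so
that classes adjacent in the mass grading share no band — and (b) total
integrated mass, graded geometrically (×1.18 per class). Shell amplitudes
scale as 1/radius so every occupied band carries similar energy. This
construction makes the class signature nearly rotation-invariant (shells
are exactly so; the blob decorations carry ~15 % of the mass), which is
what lets a plain nearest-centroid classifier on raw voxels separate clean
classes at ≥95 % despite fully random per-volume rotations — the
generator's learnability control. A candidate class whose canonical-pose
density correlates above 0.85 (NCC) with an accepted class is redrawn.

Per volume: the target motif gets a uniform random rotation and ~1-voxel
translation (well inside the required central third); a uniform count of
neighbour motifs (default 2–6) of random class and pose is superimposed
with centroids outside the central third (overlap with the target is
allowed — that is the crowding challenge); the missing wedge is applied;
and noise is added. The missing wedge follows single-axis tilt geometry
(tilt axis y, beam axis z): frequency (kx, ky, kz) is zeroed iff
`0 < |kx| < |kz|·tan(half-angle)`, a double wedge about the kz axis,
conjugate-symmetric, with the degenerate kx = 0 plane treated as measured
so the wedge vanishes continuously as the half-angle → 0. Default
half-angle 30° (a ±60° tilt scheme).

SNR is defined as Var(signal)/Var(noise). In `generate_dataset` /
`simulate_volume` the noise field is itself wedge-filtered and then scaled
to exactly Var(signal)/snr, so generated volumes keep both properties at
once: masked Fourier coefficients exactly zero, and empirical SNR equal to
the configured value in expectation. (The standalone `add_noise_at_snr`
adds plain white noise.) Geometry and noise use independent seed streams,
so regenerating a dataset at a different SNR with the same seed yields the
identical underlying signal — which is how the calibration tests estimate
the realized SNR. Splits are per-class seeded shuffles partitioned by
largest-remainder rounding (ties resolve train → val → test, so a single
record lands in train); identical configurations produce bit-identical
volumes and manifests.

What the generator does **not** emulate: electron-optical modulation
(CTF/MTF), structured cellular background, tomographic reconstruction
artefacts beyond the wedge, and real macromolecular density. Passing tests
therefore demonstrate that the machinery behaves as specified under
controlled statistics, not that a given accuracy transfers to experimental
data.

## Training defaults

Pretraining: queue 128 (64 in the benchmark, matching its small training
split), m = 0.999, τ = 0.2, Adam lr 1e-4, weight decay 1e-4, batch 16, 200
epochs; incomplete trailing batches are dropped so FIFO replacement stays
block-aligned (queue size must divide by batch size). Fine-tuning: all
layers unfrozen, cross-entropy, SGD with classical momentum 0.9, cosine
decay from lr 5e-4, weight decay 1e-4, batch 16, 50 epochs, checkpoint at
the best validation accuracy (ties → earliest epoch). Momentum is a
deliberate addition: the upstream description says only "SGD with cosine
decay", but at desk scale (~10² updates) momentum-free SGD at lr 5e-4
leaves the network near its initialization and the semi-supervised
comparison would measure noise. Label subsets are stratified per class
(largest-remainder allocation, exact total = round(fraction × |train|))
and resampled per repeat run, so reported spreads cover subset choice and
initialization; labelled flags can never touch validation/test records
(manifest validation rejects leakage).

## Scaled-down benchmark

`benchmark.run_pretraining_benefit` fixes the desk-scale study: 3 classes ×
50 volumes at 16³, SNR 0.5, wedge 30°, 1–3 neighbours; tiny encoder; MoCo
pretraining for 20 epochs; fine-tuning for 15 epochs (the 50-epoch default
scaled by the same 10× factor as pretraining) at 25 % and 100 % labels from
both pretrained and random initialization; 3 independent seeds. These sizes
are the package's chosen desk-scale operating point; they complete in
roughly a quarter hour on one CPU. The qualitative outcomes it checks:
pretraining loss decreases epoch over epoch; pretrained initialization is
at least as good as random at 25 % labels (in practice ~10–15 accuracy
points better); more labels never hurt either method; positive pairs embed
closer than negatives on held-out volumes.

## Numerical choices and degenerate inputs

- Gradient checks: float32 forward noise limits finite-difference agreement
  to ~5 % relative at ε = 1e-3; loss-level gradients computed in float64
  (contrastive, in-batch, t-test) are validated to 1e-6 or tighter.
- Max pooling breaks ties toward the first index; pooling requires even
  spatial dims, enforced at configuration time (`in_side` divisible by
  2^stages, error names the offending stage).
- Constant volumes z-score to all zeros; zero-variance signals reject a
  finite-SNR request (the ratio is undefined).
- Sub-voxel motif features alias, so rendered component widths are floored
  at 0.55 voxel.
- A pose pushing any motif component centre within 2 voxels of the box edge
  is resampled (bounded retries); an explicitly supplied out-of-bounds pose
  raises. Neighbour motifs may clip at box borders, as real crowding does.
- `compare_methods` with two zero-variance samples raises unless the means
  are also equal (then t = 0, p = 1, the degenerate null).
- All randomness flows from `numpy` `SeedSequence` spawning; every CLI
  command is bit-reproducible for a fixed seed on one machine.

## Known limitations

- Pure-numpy training limits practical sizes to the tiny/benchmark regime;
  the full-size encoder builds and runs forward passes but is not trained
  in the test suite.
- The momentum coefficient 0.999 is tuned for long schedules; at 10² steps
  the key encoder stays close to its initialization, so desk-scale
  pretraining gains are smaller than full-scale runs would show.
- The generator's classes are parametric phantoms; none of the results here
  quantify performance on experimentally acquired subtomograms.
- SwAV-style clustering pretraining and CTF/MTF simulation are out of
  scope.
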