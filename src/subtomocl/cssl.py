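"""Contrastive self-supervised pretraining.

Two training schemes over the same augmented-pair machinery:

* **Momentum-contrast (MoCo-style)**: a query encoder is trained by gradient
  descent while a key encoder tracks it as an exponential running average,
  θ_k ← m·θ_k + (1 − m)·θ_q. Negatives come from a fixed-length FIFO queue of
  historical key embeddings; each step the current keys replace the oldest
  mini-batch. The loss for query q_j with positive key k_j, temperature τ and
  queue {k_i} is

      L = −log [ exp(q_j·k_j/τ) / ( exp(q_j·k_j/τ) + Σ_i exp(q_j·k_i/τ) ) ],

  averaged over the batch (the positive similarity appears in the
  denominator alongside the queue terms, i.e. a softmax over 1 + K logits).

* **In-batch contrast (SimCLR-style)**: one encoder embeds both views of the
  whole batch; each view's negatives are the other 2(B − 1) views, same loss
  form, no queue or momentum encoder.

Embeddings are unit-norm, so q·k is a cosine similarity and τ = 0.2 scales
it on the unit sphere. Pretraining never reads class labels: the data loader
hands the loop volumes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import Adam
from .augment import AugmentPolicy, augment_view, make_pair
from .encoder import Encoder, EncoderConfig, ModelWeights


@dataclass
class PretrainConfig:
    """Pretraining hyperparameters (defaults are the operative settings:
    queue 128, m = 0.999, τ = 0.2, Adam lr 1e-4 / wd 1e-4, batch 16,
    200 epochs)."""

    queue_size: int = 128
    momentum: float = 0.999
    temperature: float = 0.2
    lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 16
    epochs: int = 200

    def __post_init__(self):
        if not (0.0 <= self.momentum <= 1.0):
            raise ValueError("momentum must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.queue_size < self.batch_size:
            raise ValueError("queue_size must be >= batch_size")
        if self.queue_size % self.batch_size:
            raise ValueError("queue_size must be divisible by batch_size")


class UnlabelledVolumes:
    """Label-blind view of a training split: exposes volumes, nothing else."""

    def __init__(self, volumes: np.ndarray):
        self.volumes = np.asarray(volumes, dtype=np.float32)
        if self.volumes.ndim != 4:
            raise ValueError("expected (N, S, S, S) volume stack")

    def __len__(self) -> int:
        return self.volumes.shape[0]

    def __getitem__(self, i) -> np.ndarray:
        return self.volumes[i]


def _validate_embeddings(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or Inf")
    return arr


def contrastive_loss(
    q: np.ndarray, k_pos: np.ndarray, queue: np.ndarray, tau: float
) -> float:
    """Queue-based contrastive loss, mean over the batch."""
    loss, _ = contrastive_loss_and_grad(q, k_pos, queue, tau)
    return loss


def contrastive_loss_and_grad(
    q: np.ndarray, k_pos: np.ndarray, queue: np.ndarray, tau: float
):
    """Loss plus its gradient with respect to the query embeddings.

    Keys and queue entries are treated as constants (keys are produced by the
    momentum encoder, which receives no gradients).
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    q = _validate_embeddings("q", q)
    k_pos = _validate_embeddings("k_pos", k_pos)
    queue = _validate_embeddings("queue", queue)
    if q.shape != k_pos.shape or q.shape[1] != queue.shape[1]:
        raise ValueError("embedding dimensions do not match")
    B = q.shape[0]
    logits = np.concatenate(
        [(q * k_pos).sum(axis=1, keepdims=True), q @ queue.T], axis=1
    ) / tau  # (B, 1 + K)
    m = logits.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
    loss = float((lse - logits[:, 0]).mean())
    p = np.exp(logits - lse[:, None])
    dlogits = p.copy()
    dlogits[:, 0] -= 1.0
    dlogits /= B
    dq = (dlogits[:, :1] * k_pos + dlogits[:, 1:] @ queue) / tau
    return loss, dq


def simclr_loss_and_grad(z: np.ndarray, tau: float):
    """In-batch contrastive loss over 2B stacked views.

    ``z`` rows are unit embeddings ordered [view-1 of batch; view-2 of batch];
    row i's positive is row (i + B) mod 2B and its negatives are every other
    row except itself. Returns (loss, dL/dz).
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    z = _validate_embeddings("z", z)
    n = z.shape[0]
    if n < 4 or n % 2:
        raise ValueError("need an even number >= 4 of views (batch size >= 2)")
    B = n // 2
    pos = (np.arange(n) + B) % n
    S = (z @ z.T) / tau
    np.fill_diagonal(S, -np.inf)
    m = S.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(S - m).sum(axis=1))
    loss = float((lse - S[np.arange(n), pos]).mean())
    P = np.exp(S - lse[:, None])  # rows sum to 1, zero diagonal
    G = P.copy()
    G[np.arange(n), pos] -= 1.0
    G /= n * tau
    dz = (G + G.T) @ z
    return loss, dz


def enqueue_dequeue(queue: np.ndarray, ptr: int, new_keys: np.ndarray):
    """Replace the oldest mini-batch of keys; returns (queue, ptr) copies."""
    K = queue.shape[0]
    B = new_keys.shape[0]
    if B > K:
        raise ValueError(f"batch of {B} keys does not fit a queue of {K}")
    if not (0 <= ptr < K):
        raise ValueError("queue pointer out of range")
    out = queue.copy()
    idx = (ptr + np.arange(B)) % K
    out[idx] = new_keys
    return out, int((ptr + B) % K)


def momentum_update(theta_q: dict, theta_k: dict, m: float) -> None:
    """Exponential running average θ_k ← m·θ_k + (1 − m)·θ_q, in place.

    The gradient step on θ_q is the optimizer's job and precedes this call in
    the training loop."""
    if not (0.0 <= m <= 1.0):
        raise ValueError("momentum must lie in [0, 1]")
    if set(theta_q) != set(theta_k):
        raise ValueError("parameter structure mismatch")
    for name, pk in theta_k.items():
        pq = theta_q[name]
        if pk.shape != pq.shape:
            raise ValueError(f"shape mismatch for {name}")
        pk *= m
        pk += (1.0 - m) * pq


def init_queue(K: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """Random unit-norm queue rows."""
    queue = rng.normal(size=(K, L))
    queue /= np.linalg.norm(queue, axis=1, keepdims=True)
    return queue


def warm_queue(
    data: UnlabelledVolumes,
    enc_k: Encoder,
    policy: AugmentPolicy,
    K: int,
    batch_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill the queue with key-encoder embeddings of augmented volumes.

    Random-vector initialization makes the first training steps artificially
    easy (random negatives are near-orthogonal to every query), which
    distorts the early loss trajectory; seeding with real keys starts the
    loss at its natural near-uniform level ~ln(K+1).
    """
    rows = []
    while sum(len(r) for r in rows) < K:
        idx = rng.integers(len(data), size=batch_size)
        xk = np.stack([augment_view(data[i], policy, rng) for i in idx])
        rows.append(enc_k.embed(xk, keep=False))
    return np.concatenate(rows)[:K]


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n - batch_size + 1, batch_size):
        yield order[start : start + batch_size]


def pretrain_moco(
    data: UnlabelledVolumes,
    policy: AugmentPolicy,
    enc_cfg: EncoderConfig,
    hp: PretrainConfig,
    seed: int = 0,
):
    """Momentum-contrast pretraining; returns (ModelWeights, loss log).

    Per batch: draw a query/key view pair per volume, embed queries with the
    trained encoder and keys with the momentum encoder (no gradients), apply
    the queue loss, Adam-step the query encoder, EMA-update the key encoder,
    and enqueue the fresh keys. Incomplete trailing batches are dropped so
    FIFO replacement stays block-aligned.
    """
    if len(data) < hp.batch_size:
        raise ValueError("training split smaller than one batch")
    ss = np.random.SeedSequence([seed, 0x40C0])
    s_init, s_queue, s_loop = ss.spawn(3)
    enc_q = Encoder(enc_cfg, seed=int(s_init.generate_state(1)[0] % 2**31))
    enc_k = Encoder(enc_cfg, seed=0)
    enc_k.set_parameters(enc_q.parameters())  # start as an exact copy
    queue = warm_queue(
        data, enc_k, policy, hp.queue_size, hp.batch_size,
        np.random.default_rng(s_queue),
    )
    ptr = 0
    opt = Adam(enc_q.parameters(), lr=hp.lr, weight_decay=hp.weight_decay)
    rng = np.random.default_rng(s_loop)
    log = []
    for epoch in range(hp.epochs):
        losses = []
        for idx in _epoch_batches(len(data), hp.batch_size, rng):
            xq = np.empty((len(idx),) + data[0].shape, dtype=np.float32)
            xk = np.empty_like(xq)
            for row, i in enumerate(idx):
                xq[row], xk[row] = make_pair(data[i], policy, rng)
            q = enc_q.embed(xq, keep=True)
            k = enc_k.embed(xk, keep=False)
            loss, dq = contrastive_loss_and_grad(q, k, queue, hp.temperature)
            enc_q.zero_grad()
            enc_q.backward_embed(dq.astype(np.float32))
            opt.step(enc_q.grads())
            momentum_update(enc_q.parameters(), enc_k.parameters(), hp.momentum)
            queue, ptr = enqueue_dequeue(queue, ptr, k)
            # queue hygiene: rows must stay unit-norm throughout training
            norms = np.linalg.norm(queue, axis=1)
            if np.abs(norms - 1.0).max() > 1e-4:
                raise RuntimeError("queue rows drifted off the unit sphere")
            losses.append(loss)
        log.append((epoch, float(np.mean(losses))))
    weights = ModelWeights(enc_q.copy_parameters(), "cssl_pretrained", enc_cfg)
    return weights, pd.DataFrame(log, columns=["epoch", "mean_loss"])


def pretrain_simclr(
    data: UnlabelledVolumes,
    policy: AugmentPolicy,
    enc_cfg: EncoderConfig,
    hp: PretrainConfig,
    seed: int = 0,
):
    """In-batch contrastive pretraining with a single encoder."""
    if hp.batch_size < 2:
        raise ValueError("batch size must be >= 2 (no negatives otherwise)")
    if len(data) < hp.batch_size:
        raise ValueError("training split smaller than one batch")
    ss = np.random.SeedSequence([seed, 0x51C1])
    s_init, s_loop = ss.spawn(2)
    enc = Encoder(enc_cfg, seed=int(s_init.generate_state(1)[0] % 2**31))
    opt = Adam(enc.parameters(), lr=hp.lr, weight_decay=hp.weight_decay)
    rng = np.random.default_rng(s_loop)
    log = []
    for epoch in range(hp.epochs):
        losses = []
        for idx in _epoch_batches(len(data), hp.batch_size, rng):
            B = len(idx)
            views = np.empty((2 * B,) + data[0].shape, dtype=np.float32)
            for row, i in enumerate(idx):
                views[row], views[row + B] = make_pair(data[i], policy, rng)
            z = enc.embed(views, keep=True)
            loss, dz = simclr_loss_and_grad(z, hp.temperature)
            enc.zero_grad()
            enc.backward_embed(dz.astype(np.float32))
            opt.step(enc.grads())
            losses.append(loss)
        log.append((epoch, float(np.mean(losses))))
    weights = ModelWeights(enc.copy_parameters(), "cssl_pretrained", enc_cfg)
    return weights, pd.DataFrame(log, columns=["epoch", "mean_loss"])
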