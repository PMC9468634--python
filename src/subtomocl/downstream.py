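"""Supervised fine-tuning and the semi-supervised evaluation protocol.

A pretrained (or freshly initialized) encoder is trained end-to-end with
cross-entropy on the labelled fraction of the training split — SGD with a
cosine-decayed learning rate, defaults lr 5e-4, weight decay 1e-4, batch 16,
50 epochs — and the epoch with the best validation accuracy is kept (ties go
to the earliest epoch). Accuracy is percent correct argmax predictions on the
untouched test split, with no test-time augmentation.

The protocol sweeps initialization methods × label fractions
(25/50/75/100%), repeating each cell with fresh label subsets and seeds, and
compares methods with a two-tailed Student t-test on per-run accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._nn import SGD, cosine_lr, softmax_cross_entropy
from .encoder import Encoder, EncoderConfig, ModelWeights, random_weights
from .volume_io import VolumeStore, normalize_volume, subsample_labels

METHODS = ("random_init", "moco", "simclr")


@dataclass
class FinetuneConfig:
    lr: float = 5e-4
    weight_decay: float = 1e-4
    batch_size: int = 16
    epochs: int = 50
    momentum: float = 0.9  # SGD momentum (standard default; not specified upstream)

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid fine-tuning hyperparameters")


@dataclass
class ExperimentResult:
    """Per-cell record of the evaluation grid: repeated-run test accuracies
    (percent) with their mean and standard deviation."""

    method: str
    label_fraction: float
    snr: float
    per_run_accuracy: list
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self):
        acc = np.asarray(self.per_run_accuracy, dtype=float)
        if acc.size == 0 or np.any((acc < 0) | (acc > 100)):
            raise ValueError("accuracies must lie in [0, 100]")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        self.mean = float(acc.mean())
        self.std = float(acc.std(ddof=1)) if acc.size > 1 else 0.0

    @property
    def n_runs(self) -> int:
        return len(self.per_run_accuracy)


def _normalized_stack(vols: np.ndarray) -> np.ndarray:
    return np.stack([normalize_volume(v) for v in vols]).astype(np.float32)


def finetune(
    weights: ModelWeights,
    train_vols: np.ndarray,
    train_labels: np.ndarray,
    val_vols: np.ndarray,
    val_labels: np.ndarray,
    hp: FinetuneConfig,
    seed: int = 0,
):
    """Train end-to-end on labelled volumes; returns (model, history frame).

    All encoder weights are unfrozen. The returned model carries the
    parameters of the epoch with the highest validation accuracy; requesting
    0 epochs returns the initial weights unchanged.
    """
    if len(train_vols) == 0:
        raise ValueError("empty labelled training set")
    n_classes = weights.config.n_classes
    present = set(np.unique(train_labels).tolist())
    if not present <= set(range(n_classes)):
        raise ValueError("labels outside the model's class range")
    model = weights.to_encoder()
    xs = _normalized_stack(train_vols)
    xv = _normalized_stack(val_vols) if len(val_vols) else None
    opt = SGD(model.parameters(), lr=hp.lr, weight_decay=hp.weight_decay,
              momentum=hp.momentum)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF17E]))
    best = (model.copy_parameters(), -np.inf, -1)
    history = []
    for epoch in range(hp.epochs):
        opt.lr = cosine_lr(hp.lr, epoch, hp.epochs)
        order = rng.permutation(len(xs))
        losses = []
        for start in range(0, len(xs), hp.batch_size):
            idx = order[start : start + hp.batch_size]
            logits = model.forward_logits(xs[idx], keep=True)
            loss, dlogits = softmax_cross_entropy(logits, train_labels[idx])
            model.zero_grad()
            model.backward_logits(dlogits)
            opt.step(model.grads())
            losses.append(loss)
        val_acc = (
            evaluate_accuracy(model, xv, val_labels, pre_normalized=True)
            if xv is not None
            else -np.inf
        )
        history.append((epoch, float(np.mean(losses)), val_acc))
        if val_acc > best[1]:  # strict: ties keep the earliest epoch
            best = (model.copy_parameters(), val_acc, epoch)
    if hp.epochs > 0 and best[2] >= 0:
        model.set_parameters(best[0])
    hist = pd.DataFrame(history, columns=["epoch", "train_loss", "val_accuracy"])
    return model, hist


def evaluate_accuracy(
    model: Encoder,
    test_vols: np.ndarray,
    test_labels: np.ndarray,
    batch_size: int = 32,
    pre_normalized: bool = False,
) -> float:
    """Percent correct argmax predictions on a test split (no augmentation)."""
    if len(test_vols) == 0:
        raise ValueError("empty test split")
    if np.max(test_labels) >= model.cfg.n_classes:
        raise ValueError("test labels outside the model's class range")
    xs = test_vols if pre_normalized else _normalized_stack(test_vols)
    correct = 0
    for start in range(0, len(xs), batch_size):
        logits = model.forward_logits(xs[start : start + batch_size], keep=False)
        correct += int((logits.argmax(axis=1) == test_labels[start : start + batch_size]).sum())
    return 100.0 * correct / len(xs)


def compare_methods(a: ExperimentResult, b: ExperimentResult, welch: bool = False):
    """Two-sample two-tailed Student t-test on per-run accuracies.

    Pooled-variance by default; ``welch=True`` drops the equal-variance
    assumption. Returns (t, p)."""
    xa = np.asarray(a.per_run_accuracy, dtype=float)
    xb = np.asarray(b.per_run_accuracy, dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least 2 runs per result")
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
        if np.allclose(xa.mean(), xb.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both samples: t-test undefined")
    t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
    return float(t), float(p)


def run_grid(
    store: VolumeStore,
    methods,
    label_fractions,
    snr: float,
    enc_cfg: EncoderConfig,
    ft_hp: FinetuneConfig,
    n_runs: int = 5,
    seed: int = 0,
    pretrained: dict | None = None,
):
    """Evaluate every (method, label fraction) cell with repeat statistics.

    ``pretrained`` maps method name to a ModelWeights checkpoint; methods
    other than ``random_init`` that are missing from it raise. Label subsets
    are resampled per run with that run's seed, so the reported spread covers
    both subset choice and initialization. Returns (list of ExperimentResult,
    tidy per-run DataFrame).
    """
    pretrained = dict(pretrained or {})
    for meth in methods:
        if meth not in METHODS:
            raise ValueError(f"unknown method {meth!r}")
        if meth != "random_init" and meth not in pretrained:
            raise ValueError(f"no pretrained checkpoint for grid cell method={meth!r}")
    train_vols, train_labels, train_ids = store.split_arrays("train")
    val = store.split_arrays("val")
    test = store.split_arrays("test")
    id_pos = {i: p for p, i in enumerate(train_ids)}
    results, rows = [], []
    for meth in methods:
        for frac in label_fractions:
            accs = []
            for run in range(n_runs):
                run_seed = int(
                    np.random.SeedSequence(
                        [seed, METHODS.index(meth), int(frac * 1000), run]
                    ).generate_state(1)[0] % 2**31
                )
                man = subsample_labels(store.man, frac, run_seed)
                sel = man.loc[man.get("labelled", False) == True, "id"]  # noqa: E712
                idx = np.array([id_pos[i] for i in sel], dtype=int)
                if meth == "random_init":
                    w = random_weights(enc_cfg, run_seed)
                else:
                    w = pretrained[meth]
                model, _ = finetune(
                    w, train_vols[idx], train_labels[idx], val[0], val[1], ft_hp,
                    seed=run_seed,
                )
                acc = evaluate_accuracy(model, test[0], test[1])
                accs.append(acc)
                rows.append((meth, frac, snr, run, run_seed, acc))
            results.append(ExperimentResult(meth, frac, snr, accs))
    runs = pd.DataFrame(
        rows, columns=["method", "fraction", "snr", "run", "seed", "accuracy"]
    )
    return results, runs


def summarize_grid(results) -> pd.DataFrame:
    """Mean ± std table, one row per label fraction, one column per method."""
    df = pd.DataFrame(
        [
            {
                "fraction": r.label_fraction,
                "snr": r.snr,
                "method": r.method,
                "cell": f"{r.mean:.1f} ± {r.std:.1f}",
            }
            for r in results
        ]
    )
    return df.pivot_table(
        index=["fraction", "snr"], columns="method", values="cell", aggfunc="first"
    )
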