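"""Residual 3D convolutional encoder with classification and embedding heads.

The network follows the residual-block 3D CNN design used for subtomogram
classification: a stem 3x3x3 convolution, then ``n_residual_stages`` stages of
[conv → ReLU → conv] with an identity skip, each followed by 2x max pooling
and a channel-doubling transition convolution (width capped at 4x the base);
then two further residual stages at constant shape whose outputs are
concatenated channel-wise; a flatten into FC-``fc_width`` with ReLU; and two
heads on top of that shared feature: FC-``embed_dim`` (L2-normalized, used by
contrastive pretraining) and FC-``n_classes`` with softmax (used by
fine-tuning). ReLU everywhere; no normalization layers or dropout, so a
forward pass is deterministic in any mode.

``features()`` runs the network through the concatenation; ``head_logits()``
and ``head_embed()`` run the heads. Grad-CAM is the ReLU of the concatenated
activation weighted channel-wise by the spatially averaged gradient of the
target class score, upsampled to the input shape.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from collections import OrderedDict
from dataclasses import asdict, dataclass

import numpy as np
from skimage.transform import resize

from ._nn import (
    DTYPE,
    Conv3d,
    Dense,
    MaxPool3d,
    ReLU,
    l2_normalize,
    l2_normalize_backward,
    softmax,
)


@dataclass(frozen=True)
class EncoderConfig:
    in_side: int = 32
    in_channels: int = 1
    base_filters: int = 64
    n_residual_stages: int = 3
    fc_width: int = 1024
    embed_dim: int = 128
    n_classes: int = 10
    tiny_mode: bool = False
    channel_cap_mult: int = 4  # max width as a multiple of base_filters

    def __post_init__(self):
        if self.embed_dim < 8:
            raise ValueError("embed_dim must be >= 8")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        side = self.in_side
        for i in range(self.n_residual_stages):
            if side % 2:
                raise ValueError(
                    f"in_side {self.in_side} not divisible by 2 at pooling stage {i}"
                )
            side //= 2

    @classmethod
    def tiny(cls, n_classes: int = 3, in_side: int = 16) -> "EncoderConfig":
        """Desk-scale configuration (< 1e6 parameters)."""
        return cls(
            in_side=in_side,
            base_filters=8,
            n_residual_stages=2,
            fc_width=64,
            embed_dim=32,
            n_classes=n_classes,
            tiny_mode=True,
        )

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


class _ResBlock:
    """x -> ReLU(x + conv(ReLU(conv(x)))), shape preserving."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv3d(channels, channels, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(channels, channels, rng)
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        r = self.conv2.forward(self.relu1.forward(self.conv1.forward(x, keep), keep), keep)
        return self.relu_out.forward(x + r, keep)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dy)
        dr = self.conv1.backward(self.relu1.backward(self.conv2.backward(dsum)))
        return dsum + dr

    def named_layers(self):
        return [("conv1", self.conv1), ("conv2", self.conv2)]


class Encoder:
    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        F = cfg.base_filters
        cap = cfg.base_filters * cfg.channel_cap_mult
        self.stem = Conv3d(cfg.in_channels, F, rng)
        self.stem_relu = ReLU()
        self.stages = []
        c = F
        for _ in range(cfg.n_residual_stages):
            block = _ResBlock(c, rng)
            pool = MaxPool3d()
            c_next = min(2 * c, cap)
            trans = Conv3d(c, c_next, rng)
            self.stages.append((block, pool, trans, ReLU()))
            c = c_next
        self.tail_a = _ResBlock(c, rng)
        self.tail_b = _ResBlock(c, rng)
        self.feat_channels = 2 * c
        self.feat_side = cfg.in_side // 2**cfg.n_residual_stages
        flat = self.feat_channels * self.feat_side**3
        self.fc1 = Dense(flat, cfg.fc_width, rng)
        self.fc1_relu = ReLU()
        self.fc_embed = Dense(cfg.fc_width, cfg.embed_dim, rng)
        self.fc_cls = Dense(cfg.fc_width, cfg.n_classes, rng)
        self._embed_cache = None
        self._head_in_shape = None

    # -- parameter access ---------------------------------------------------

    def _named_layers(self):
        out = [("stem", self.stem)]
        for i, (block, _, trans, _) in enumerate(self.stages):
            out += [(f"stage{i}.{n}", l) for n, l in block.named_layers()]
            out.append((f"stage{i}.trans", trans))
        out += [("tail_a." + n, l) for n, l in self.tail_a.named_layers()]
        out += [("tail_b." + n, l) for n, l in self.tail_b.named_layers()]
        out += [("fc1", self.fc1), ("fc_embed", self.fc_embed), ("fc_cls", self.fc_cls)]
        return out

    def parameters(self) -> "OrderedDict[str, np.ndarray]":
        params = OrderedDict()
        for name, layer in self._named_layers():
            for pname, arr in layer.params().items():
                params[f"{name}.{pname}"] = arr
        return params

    def grads(self) -> "OrderedDict[str, np.ndarray]":
        grads = OrderedDict()
        for name, layer in self._named_layers():
            for pname, arr in layer.grads().items():
                grads[f"{name}.{pname}"] = arr
        return grads

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0

    def set_parameters(self, params: dict) -> None:
        own = self.parameters()
        if set(own) != set(params):
            raise ValueError("parameter structure mismatch")
        for k, v in own.items():
            if v.shape != params[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            v[...] = params[k]

    def copy_parameters(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, v.copy()) for k, v in self.parameters().items())

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 4:
            x = x[:, None]
        s = self.cfg.in_side
        if x.shape[1:] != (self.cfg.in_channels, s, s, s):
            raise ValueError(
                f"expected batch of {self.cfg.in_channels}x{s}^3 volumes, got {x.shape}"
            )
        return x

    def features(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        """Through the concat of the last two same-shape residual stages."""
        x = self._check_input(x)
        h = self.stem_relu.forward(self.stem.forward(x, keep), keep)
        for block, pool, trans, trelu in self.stages:
            h = block.forward(h, keep)
            h = pool.forward(h, keep)
            h = trelu.forward(trans.forward(h, keep), keep)
        ha = self.tail_a.forward(h, keep)
        hb = self.tail_b.forward(ha, keep)
        return np.concatenate([ha, hb], axis=1)

    def features_backward(self, dA: np.ndarray) -> np.ndarray:
        c = dA.shape[1] // 2
        dha = dA[:, :c] + self.tail_b.backward(dA[:, c:])
        dh = self.tail_a.backward(dha)
        for block, pool, trans, trelu in reversed(self.stages):
            dh = trans.backward(trelu.backward(dh))
            dh = pool.backward(dh)
            dh = block.backward(dh)
        return self.stem.backward(self.stem_relu.backward(dh))

    def _head_common(self, A: np.ndarray, keep: bool = True) -> np.ndarray:
        if keep:
            self._head_in_shape = A.shape
        flat = A.reshape(A.shape[0], -1)
        return self.fc1_relu.forward(self.fc1.forward(flat, keep), keep)

    def head_logits(self, A: np.ndarray, keep: bool = True) -> np.ndarray:
        return self.fc_cls.forward(self._head_common(A, keep), keep)

    def head_backward_logits(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop the head only; returns the gradient at the concat."""
        dh = self.fc1.backward(self.fc1_relu.backward(self.fc_cls.backward(dlogits)))
        return dh.reshape(self._head_in_shape)

    def forward_logits(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        return self.head_logits(self.features(x, keep), keep)

    def backward_logits(self, dlogits: np.ndarray) -> np.ndarray:
        return self.features_backward(self.head_backward_logits(dlogits))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward_logits(x, keep=False))

    def embed(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        """L2-normalized embedding vectors, shape (batch, embed_dim)."""
        h = self._head_common(self.features(x, keep), keep)
        z = self.fc_embed.forward(h, keep)
        zn, n = l2_normalize(z)
        if keep:
            self._embed_cache = (zn, n)
        return zn

    def backward_embed(self, dzn: np.ndarray) -> np.ndarray:
        zn, n = self._embed_cache
        dz = l2_normalize_backward(dzn, zn, n)
        dh = self.fc1.backward(self.fc1_relu.backward(self.fc_embed.backward(dz)))
        return self.features_backward(dh.reshape(self._head_in_shape))


# ---------------------------------------------------------------------------
# Weight containers


@dataclass
class ModelWeights:
    params: "OrderedDict[str, np.ndarray]"
    provenance: str  # random_init | cssl_pretrained
    config: EncoderConfig

    def save(self, path) -> None:
        meta = {
            "provenance": self.provenance,
            "config": asdict(self.config),
            "fingerprint": self.config.fingerprint(),
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "ModelWeights":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            params = OrderedDict(
                (k, f[k]) for k in f.files if k != "__meta__"
            )
        cfg = EncoderConfig(**meta["config"])
        if cfg.fingerprint() != meta["fingerprint"]:
            raise ValueError("checkpoint fingerprint does not match its config")
        return cls(params, meta["provenance"], cfg)

    def to_encoder(self) -> Encoder:
        enc = Encoder(self.config, seed=0)
        enc.set_parameters(self.params)
        return enc


def random_weights(cfg: EncoderConfig, seed: int) -> ModelWeights:
    enc = Encoder(cfg, seed=seed)
    return ModelWeights(enc.copy_parameters(), "random_init", cfg)


def build_encoder(cfg: EncoderConfig, seed: int = 0) -> Encoder:
    """Construct the encoder; same config and seed give identical weights."""
    return Encoder(cfg, seed=seed)


def count_parameters(model: Encoder) -> int:
    return int(sum(v.size for v in model.parameters().values()))


def gradcam(model: Encoder, vol: np.ndarray, target_class: int) -> np.ndarray:
    """3D class-activation map in [0, 1] with the input's shape.

    ReLU of the concat activation weighted per channel by the spatial mean of
    the target-logit gradient, trilinearly upsampled and max-normalized. An
    everywhere-zero map (dead gradients) is returned as-is with a warning.
    """
    x = np.asarray(vol, dtype=DTYPE)[None]
    A = model.features(x, keep=True)
    logits = model.head_logits(A, keep=True)
    if not (0 <= target_class < logits.shape[1]):
        raise ValueError(f"target_class {target_class} out of range")
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    dA = model.head_backward_logits(dlogits)
    w = dA.mean(axis=(2, 3, 4))  # (1, C)
    cam = np.maximum((w[:, :, None, None, None] * A).sum(axis=1), 0.0)[0]
    s = model.cfg.in_side
    cam = resize(cam.astype(np.float64), (s, s, s), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    cam = np.maximum(cam, 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    else:
        warnings.warn("Grad-CAM gradients vanished; returning an all-zero map")
    return cam
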