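"""Stochastic 3D augmentations that manufacture contrastive positive pairs.

The pipeline is deliberately mild — cryo-ET subtomograms are small and
low-contrast, and aggressive photometric augmentation destroys the features a
contrastive model needs. Two operations are used, each gated by an
independent 50% Bernoulli draw per view:

* a random resized crop: a cubic sub-block covering a volume fraction in
  [0.5, 1] is cut at a random position and resampled back to full size;
* a random affine resampling composed, in fixed order, of isotropic scaling
  (factor within ±0.1 of 1), rotation about the z axis (angle within ±45°),
  and in-plane (x, y) translation (each within ±0.1 of the side).

Volumes are indexed ``[x, y, z]``; a +90° z-rotation carries a feature at
offset (+a, 0, 0) from the centre to (0, +a, 0). Both views of a pair are
z-score normalized after augmentation. Augmentations never see labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform
from skimage.transform import resize

from .volume_io import normalize_volume


@dataclass
class AugmentPolicy:
    """Validated configuration of the augmentation pipeline (defaults are the
    operative values of the method)."""

    p_crop: float = 0.5
    crop_scale_range: tuple = (0.5, 1.0)
    p_affine: float = 0.5
    rot_range_deg: tuple = (-45.0, 45.0)
    trans_frac_max: float = 0.1
    scale_frac_max: float = 0.1
    interp_order: int = 1
    fill_mode: str = "constant"  # constant-zero | mirror
    crop_mode: str = "volume"  # crop scale as volume fraction or side fraction

    def __post_init__(self):
        if not (0.0 <= self.p_crop <= 1.0 and 0.0 <= self.p_affine <= 1.0):
            raise ValueError("gate probabilities must lie in [0, 1]")
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_scale_range must be a subinterval of (0, 1]")
        rlo, rhi = self.rot_range_deg
        if not (-180.0 < rlo <= rhi < 180.0):
            raise ValueError("rot_range_deg must lie within (-180, 180)")
        if not (0.0 <= self.trans_frac_max < 0.5):
            raise ValueError("trans_frac_max must lie in [0, 0.5)")
        if not (0.0 <= self.scale_frac_max < 1.0):
            raise ValueError("scale_frac_max must lie in [0, 1)")
        if self.fill_mode not in ("constant", "mirror"):
            raise ValueError("fill_mode must be 'constant' or 'mirror'")
        if self.crop_mode not in ("volume", "side"):
            raise ValueError("crop_mode must be 'volume' or 'side'")


def _check_cubic(vol: np.ndarray) -> int:
    if vol.ndim != 3 or len(set(vol.shape)) != 1:
        raise ValueError(f"expected a cubic volume, got shape {vol.shape}")
    return vol.shape[0]


def crop_side(side: int, scale: float, crop_mode: str = "volume") -> int:
    """Side of the crop covering ``scale`` of the volume (cube-root law) or of
    the side, before resampling back to full size."""
    frac = scale ** (1.0 / 3.0) if crop_mode == "volume" else scale
    return int(round(side * frac))


def random_resized_crop(
    vol: np.ndarray,
    scale_range: tuple = (0.5, 1.0),
    rng: np.random.Generator | None = None,
    interp_order: int = 1,
    crop_mode: str = "volume",
) -> np.ndarray:
    side = _check_cubic(vol)
    if side < 8:
        raise ValueError("volume side must be >= 8")
    if crop_side(side, scale_range[0], crop_mode) < 4:
        raise ValueError("crop_scale_range lower bound yields a crop side < 4")
    rng = np.random.default_rng() if rng is None else rng
    scale = rng.uniform(*scale_range)
    cs = max(4, crop_side(side, scale, crop_mode))
    corner = rng.integers(0, side - cs + 1, size=3)
    crop = vol[
        corner[0] : corner[0] + cs,
        corner[1] : corner[1] + cs,
        corner[2] : corner[2] + cs,
    ]
    if cs == side:
        return crop.astype(np.float64, copy=True)
    return resize(
        crop.astype(np.float64),
        (side, side, side),
        order=interp_order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def _zrot(angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    # +angle carries +x toward +y in the (x, y) index plane
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def affine_resample(
    vol: np.ndarray,
    angle_deg: float = 0.0,
    translation=(0.0, 0.0, 0.0),
    scale: float = 1.0,
    interp_order: int = 1,
    fill_mode: str = "constant",
) -> np.ndarray:
    """Single-pass resampling of scale → z-rotation → translation about the
    volume centre: y = t + R·s·(v − c) + c."""
    side = _check_cubic(vol)
    c = (side - 1) / 2.0
    t = np.asarray(translation, dtype=float)
    R = _zrot(angle_deg)
    # affine_transform pulls: in_coord = A @ out_coord + offset, A = (R s)^-1
    A = R.T / scale
    offset = c * np.ones(3) - A @ (c + t)
    # snap grid-aligned transforms (90° turns, integer shifts) to exactness
    A = np.where(np.abs(A - np.round(A)) < 1e-12, np.round(A), A)
    offset = np.where(np.abs(offset - np.round(offset)) < 1e-9, np.round(offset), offset)
    mode = "constant" if fill_mode == "constant" else "mirror"
    return affine_transform(
        vol.astype(np.float64), A, offset=offset, order=interp_order,
        mode=mode, cval=0.0,
    )


def sample_affine_params(policy: AugmentPolicy, side: int, rng: np.random.Generator):
    """Draw (angle, (tx, ty, 0), scale) from the policy ranges."""
    angle = rng.uniform(*policy.rot_range_deg)
    tx, ty = rng.uniform(-policy.trans_frac_max, policy.trans_frac_max, size=2) * side
    scale = rng.uniform(1.0 - policy.scale_frac_max, 1.0 + policy.scale_frac_max)
    return angle, (tx, ty, 0.0), scale


def random_affine(
    vol: np.ndarray, policy: AugmentPolicy, rng: np.random.Generator
) -> np.ndarray:
    side = _check_cubic(vol)
    angle, t, scale = sample_affine_params(policy, side, rng)
    return affine_resample(
        vol, angle, t, scale, policy.interp_order, policy.fill_mode
    )


def augment_view(
    vol: np.ndarray, policy: AugmentPolicy, rng: np.random.Generator
) -> np.ndarray:
    """One stochastic draw of the pipeline followed by z-score normalization."""
    out = vol
    if rng.random() < policy.p_crop:
        out = random_resized_crop(
            out, policy.crop_scale_range, rng, policy.interp_order, policy.crop_mode
        )
    if rng.random() < policy.p_affine:
        out = random_affine(out, policy, rng)
    return normalize_volume(out)


def make_pair(
    vol: np.ndarray, policy: AugmentPolicy, rng: np.random.Generator
):
    """Two independent augmented (and normalized) views of one volume — the
    query/key positive pair of contrastive pretraining."""
    return augment_view(vol, policy, rng), augment_view(vol, policy, rng)
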