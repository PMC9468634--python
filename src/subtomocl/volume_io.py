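"""Reading and writing subtomogram volumes and dataset manifests.

Volumes are cubic (or at least 3D) density grids stored either as MRC/CCP4
maps (mode 2, float32, one file per subtomogram) or as datasets inside a
single HDF5 container (``file.h5::/volumes/<id>``). Manifests are CSV files
with one row per subtomogram: ``id, path, class_id, split`` plus an optional
``labelled`` flag used by the semi-supervised protocol.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import h5py
import numpy as np
import pandas as pd

SPLITS = ("train", "val", "test")

HDF5_SEP = "::"


def write_volume(path: str | os.PathLike, vol: np.ndarray) -> None:
    """Write a 3D volume.

    ``path`` ending in ``.mrc``/``.map`` writes an MRC mode-2 (float32) map;
    a path of the form ``file.h5::/volumes/<id>`` writes an HDF5 dataset.
    """
    spath = str(path)
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {vol.shape} for {spath}")
    if HDF5_SEP in spath:
        fname, dset = spath.split(HDF5_SEP, 1)
        with h5py.File(fname, "a") as f:
            if dset in f:
                del f[dset]
            f.create_dataset(dset, data=vol.astype(np.float32))
        return
    suffix = Path(spath).suffix.lower()
    if suffix in (".mrc", ".map", ".ccp4"):
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(vol.astype(np.float32)))
        m.update_ccp4_header()
        m.write_ccp4_map(spath)
    elif suffix in (".h5", ".hdf5"):
        raise ValueError(
            f"HDF5 paths must name a dataset: use '{spath}{HDF5_SEP}/volumes/<id>'"
        )
    else:
        raise ValueError(f"unsupported volume format: {spath}")


def read_volume(path: str | os.PathLike) -> np.ndarray:
    """Read a 3D volume written by :func:`write_volume`.

    Returns a float32 array with the shape recorded in the file header;
    voxel values are returned unchanged.
    """
    spath = str(path)
    if HDF5_SEP in spath:
        fname, dset = spath.split(HDF5_SEP, 1)
        with h5py.File(fname, "r") as f:
            if dset not in f:
                raise ValueError(f"dataset {dset!r} not found in {fname}")
            vol = f[dset][()]
    else:
        try:
            m = gemmi.read_ccp4_map(spath)
        except (RuntimeError, ValueError, OSError) as e:
            raise ValueError(f"failed to parse volume file {spath}: {e}") from e
        vol = np.array(m.grid, copy=True)
    vol = np.asarray(vol, dtype=np.float32)
    if vol.ndim != 3:
        raise ValueError(f"volume in {spath} is not 3D (shape {vol.shape})")
    return vol


def normalize_volume(vol: np.ndarray) -> np.ndarray:
    """Per-volume z-score: zero mean, unit variance.

    Constant volumes map to all-zeros. NaN/Inf input is rejected.
    """
    vol = np.asarray(vol, dtype=np.float64)
    if not np.all(np.isfinite(vol)):
        raise ValueError("volume contains NaN or Inf")
    sd = vol.std()
    if sd == 0.0:
        return np.zeros_like(vol, dtype=np.float32)
    return ((vol - vol.mean()) / sd).astype(np.float32)


# ---------------------------------------------------------------------------
# Manifests


def validate_manifest(man: pd.DataFrame) -> None:
    required = {"id", "path", "class_id", "split"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if man["id"].duplicated().any():
        raise ValueError("manifest ids are not unique")
    bad = set(man["split"]) - set(SPLITS)
    if bad:
        raise ValueError(f"unknown split values: {sorted(bad)}")
    if (man["class_id"] < 0).any():
        raise ValueError("negative class_id")
    if "labelled" in man.columns:
        leak = man.loc[man["split"] != "train", "labelled"]
        if leak.astype(bool).any():
            raise ValueError("labelled flags outside the training split (leakage)")


def write_manifest(man: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_manifest(man)
    man.to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    man = pd.read_csv(path)
    if "labelled" in man.columns:
        man["labelled"] = man["labelled"].astype(bool)
    validate_manifest(man)
    return man


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``targets`` (reals)."""
    base = np.floor(targets).astype(int)
    rem = total - base.sum()
    if rem < 0:  # all-ceil corner case
        order = np.argsort(targets - base)
        base[order[: -rem]] -= 1
        rem = 0
    order = np.argsort(-(targets - base))  # largest fractional parts first
    base[order[:rem]] += 1
    return base


def subsample_labels(man: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Flag a stratified random subset of training records as labelled.

    Exactly ``round(fraction * n_train)`` training records are flagged,
    allocated across classes proportionally to their training counts
    (largest-remainder rounding, so per-class counts differ from the exact
    proportion by at most 1). Validation/test records are never flagged.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    validate_manifest(man)
    man = man.copy()
    train = man[man["split"] == "train"]
    n_total = int(round(fraction * len(train)))
    classes = np.sort(train["class_id"].unique())
    counts = np.array([(train["class_id"] == c).sum() for c in classes], dtype=float)
    alloc = _largest_remainder(counts * n_total / counts.sum(), n_total)
    if (alloc == 0).any():
        bad = classes[alloc == 0].tolist()
        raise ValueError(
            f"fraction {fraction} leaves classes {bad} with no labelled records"
        )
    rng = np.random.default_rng(seed)
    labelled_ids: list = []
    for c, k in zip(classes, alloc):
        ids = train.loc[train["class_id"] == c, "id"].to_numpy()
        pick = rng.choice(len(ids), size=int(k), replace=False)
        labelled_ids.extend(ids[np.sort(pick)])
    man["labelled"] = man["id"].isin(labelled_ids) & (man["split"] == "train")
    validate_manifest(man)
    return man


class VolumeStore:
    """Lazy cache of manifest volumes, keyed by record id.

    Paths in the manifest are resolved relative to ``root`` (defaults to the
    manifest's own directory when loaded via :func:`read_manifest`).
    """

    def __init__(self, man: pd.DataFrame, root: str | os.PathLike = "."):
        validate_manifest(man)
        self.man = man.reset_index(drop=True)
        self.root = Path(root)
        self._cache: dict = {}

    def _resolve(self, path: str) -> str:
        if HDF5_SEP in path:
            fname, dset = path.split(HDF5_SEP, 1)
            if not os.path.isabs(fname):
                fname = str(self.root / fname)
            return fname + HDF5_SEP + dset
        return path if os.path.isabs(path) else str(self.root / path)

    def get(self, rec_id) -> np.ndarray:
        if rec_id not in self._cache:
            row = self.man.loc[self.man["id"] == rec_id]
            if len(row) != 1:
                raise KeyError(f"id {rec_id!r} not in manifest")
            self._cache[rec_id] = read_volume(self._resolve(row["path"].iloc[0]))
        return self._cache[rec_id]

    def split_arrays(self, split: str, labelled_only: bool = False):
        """Return (volumes (N,S,S,S) float32, labels (N,), ids) for a split."""
        sub = self.man[self.man["split"] == split]
        if labelled_only:
            if "labelled" not in sub.columns:
                raise ValueError("manifest has no labelled column")
            sub = sub[sub["labelled"]]
        vols = np.stack([self.get(i) for i in sub["id"]]).astype(np.float32)
        return vols, sub["class_id"].to_numpy(), sub["id"].to_numpy()
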