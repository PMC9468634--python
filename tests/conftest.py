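import numpy as np
import pytest

import subtomocl.synthetic_data as sd


@pytest.fixture(scope="session")
def class_library():
    """Three structure classes used across tests."""
    return sd.make_structure_classes(3, seed=17)


@pytest.fixture(scope="session")
def tiny_dataset(class_library):
    """In-memory 3-class dataset at 16^3 with crowding, wedge and noise.

    Returns (volumes, labels, split index arrays) with a class-balanced
    30/10/10 per-class train/val/test partition.
    """
    cfg = sd.SimulationConfig(
        side_length=16, n_classes=3, per_class=50, n_neighbors_range=(1, 3),
        snr=0.5, wedge_half_angle=30.0, seed=42,
    )
    ss = np.random.SeedSequence(7).spawn(300)
    vols, labels = [], []
    for cid in range(3):
        for j in range(50):
            i = (cid * 50 + j) * 2
            vols.append(sd.simulate_volume(cfg, class_library, cid, ss[i], ss[i + 1]))
            labels.append(cid)
    vols = np.asarray(vols, dtype=np.float32)
    labels = np.asarray(labels)
    train = np.concatenate([np.arange(c * 50, c * 50 + 30) for c in range(3)])
    val = np.concatenate([np.arange(c * 50 + 30, c * 50 + 40) for c in range(3)])
    test = np.concatenate([np.arange(c * 50 + 40, c * 50 + 50) for c in range(3)])
    return vols, labels, train, val, test


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def unit_rows(rng, n, d):
    x = rng.normal(size=(n, d))
    return x / np.linalg.norm(x, axis=1, keepdims=True)
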