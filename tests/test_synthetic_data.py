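"""Generator tests: motif rendering, crowding, missing wedge, SNR, splits."""

import math

import numpy as np
import pandas as pd
import pytest

import subtomocl.synthetic_data as sd
from subtomocl.volume_io import VolumeStore


class TestStructureClasses:
    def test_pairwise_ncc_below_bound(self):
        classes = sd.make_structure_classes(10, seed=1)
        dens = [sd.render_structure(c, 32, sd.IDENTITY_POSE) for c in classes]
        for i in range(10):
            for j in range(i):
                assert sd._class_ncc(dens[i], dens[j]) < 0.9

    def test_motif_fits_with_margin(self):
        for cls in sd.make_structure_classes(5, seed=3):
            dens = sd.render_structure(cls, 32, sd.IDENTITY_POSE)
            # border shells two voxels thick carry a negligible share of mass
            border = dens.copy()
            border[2:-2, 2:-2, 2:-2] = 0.0
            assert border.sum() < 0.05 * dens.sum()

    def test_density_non_negative(self):
        cls = sd.make_structure_classes(3, seed=5)[1]
        dens = sd.render_structure(cls, 16, sd.IDENTITY_POSE)
        assert dens.min() >= 0.0


class TestRenderStructure:
    def test_identity_pose_centroid_at_center(self, class_library):
        dens = sd.render_structure(class_library[0], 32, sd.IDENTITY_POSE)
        com = np.array(
            [(dens.sum(axis=tuple(a for a in range(3) if a != ax)) *
              np.arange(32)).sum() for ax in range(3)]
        ) / dens.sum()
        assert np.allclose(com, 15.5, atol=0.5)

    def test_90deg_z_rotation_permutes_axes(self, class_library):
        """A +90° z-rotation must carry mass from (+a,0,0) to (0,+a,0),
        i.e. match an explicit grid-axis permutation."""
        cls = class_library[2]
        R90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        rotated = sd.render_structure(cls, 16, sd.Pose(R90, np.zeros(3)))
        canonical = sd.render_structure(cls, 16, sd.IDENTITY_POSE)
        assert np.allclose(rotated, np.rot90(canonical, 1, axes=(0, 1)), atol=1e-12)

    def test_seeded_determinism(self, class_library):
        a = sd.render_structure(class_library[0], 16, rng=np.random.default_rng(5))
        b = sd.render_structure(class_library[0], 16, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_invalid_poses_rejected(self, class_library):
        bad_rot = sd.Pose(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValueError):
            sd.render_structure(class_library[0], 16, bad_rot)
        off_center = sd.Pose(np.eye(3), np.array([10.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            sd.render_structure(class_library[0], 16, off_center)


class TestAddNeighbors:
    def test_zero_neighbors_is_identity(self, class_library, rng):
        vol = sd.render_structure(class_library[0], 16, sd.IDENTITY_POSE)
        out = sd.add_neighbors(vol, class_library, 0, rng)
        np.testing.assert_array_equal(out, vol)

    def test_neighbors_add_density(self, class_library, rng):
        vol = sd.render_structure(class_library[0], 16, sd.IDENTITY_POSE)
        out = sd.add_neighbors(vol, class_library, 3, rng)
        assert out.sum() > vol.sum()
        assert np.all(out >= vol - 1e-12)  # superposition never removes mass

    def test_seeded_determinism(self, class_library):
        vol = sd.render_structure(class_library[1], 16, sd.IDENTITY_POSE)
        a = sd.add_neighbors(vol, class_library, 2, np.random.default_rng(9))
        b = sd.add_neighbors(vol, class_library, 2, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestMissingWedge:
    def test_tiny_wedge_is_identity(self, rng):
        vol = rng.normal(size=(16, 16, 16))
        out = sd.apply_missing_wedge(vol, 1e-4)
        assert np.abs(out - vol).max() < 1e-9

    def test_output_real_and_shape_preserved(self, rng):
        vol = rng.normal(size=(16, 16, 16))
        spec = np.fft.fftn(vol)
        spec[sd.wedge_mask(16, 30.0)] = 0.0
        back = np.fft.ifftn(spec)
        assert np.abs(back.imag).max() < 1e-6 * np.linalg.norm(back.real)
        assert sd.apply_missing_wedge(vol, 30.0).shape == vol.shape

    def test_delta_function_zero_count_matches_enumeration(self):
        """The number of zeroed coefficients for a delta input equals a direct
        enumeration of frequency vectors inside the double wedge."""
        side, angle = 16, 30.0
        delta = np.zeros((side,) * 3)
        delta[side // 2] = 0.0
        delta[8, 8, 8] = 1.0
        spec = np.fft.fftn(sd.apply_missing_wedge(delta, angle))
        zeroed = int((np.abs(spec) < 1e-12).sum())
        k = np.fft.fftfreq(side)
        expected = sum(
            side  # every ky
            for kx in k
            for kz in k
            if 0 < abs(kx) < abs(kz) * math.tan(math.radians(angle))
        )
        assert zeroed == expected

    def test_non_cubic_rejected(self):
        with pytest.raises(ValueError):
            sd.apply_missing_wedge(np.zeros((8, 8, 4)), 30.0)


class TestNoise:
    def test_infinite_snr_returns_input(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        np.testing.assert_array_equal(sd.add_noise_at_snr(vol, math.inf, rng), vol)

    @pytest.mark.parametrize("snr", [0.05, 1.0])
    def test_noise_variance_matches_snr(self, rng, snr):
        """Empirical noise variance approximates Var(signal)/snr at 32^3
        (so snr=0.05 on a unit-variance signal gives variance ~20)."""
        vol = rng.normal(size=(32, 32, 32))
        vol /= vol.std()
        noise = sd.add_noise_at_snr(vol, snr, rng) - vol
        expected_var = vol.var() / snr
        assert 0.9 * expected_var <= noise.var() <= 1.1 * expected_var

    def test_zero_variance_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            sd.add_noise_at_snr(np.ones((8, 8, 8)), 1.0, rng)


class TestSplitsAndDataset:
    @pytest.mark.parametrize(
        "per_class,n_classes,ratios,expected",
        [
            (500, 10, (0.6, 0.2, 0.2), (3000, 1000, 1000)),
            (400, 7, (0.6, 0.2, 0.2), (1680, 560, 560)),
        ],
    )
    def test_split_arithmetic(self, per_class, n_classes, ratios, expected):
        counts = sd._split_counts(per_class, ratios) * n_classes
        assert tuple(counts) == expected

    def test_single_record_goes_to_train(self):
        assert tuple(sd._split_counts(1, (0.6, 0.2, 0.2))) == (1, 0, 0)

    def test_generate_dataset_balanced_and_deterministic(self, tmp_path):
        cfg = sd.SimulationConfig(
            side_length=16, n_classes=3, per_class=10, n_neighbors_range=(0, 1),
            snr=0.5, wedge_half_angle=30.0, seed=3,
        )
        man = sd.generate_dataset(cfg, tmp_path / "a")
        assert len(man) == 30
        per_split = man.groupby(["split", "class_id"]).size()
        for c in range(3):
            assert per_split[("train", c)] == 6
            assert per_split[("val", c)] == 2
            assert per_split[("test", c)] == 2
        man2 = sd.generate_dataset(cfg, tmp_path / "b")
        pd.testing.assert_frame_equal(man, man2)
        va = VolumeStore(man, tmp_path / "a").get(man["id"].iloc[7])
        vb = VolumeStore(man2, tmp_path / "b").get(man["id"].iloc[7])
        np.testing.assert_array_equal(va, vb)

    def test_generated_volumes_keep_wedge_zeros(self, tmp_path):
        cfg = sd.SimulationConfig(
            side_length=16, n_classes=2, per_class=4, n_neighbors_range=(0, 0),
            snr=0.1, wedge_half_angle=30.0, seed=5,
        )
        man = sd.generate_dataset(cfg, tmp_path)
        store = VolumeStore(man, tmp_path)
        mask = sd.wedge_mask(16, 30.0)
        for rec_id in man["id"]:
            spec = np.fft.fftn(store.get(rec_id))
            assert np.abs(spec[mask]).max() < 1e-4 * np.abs(spec).max()

    def test_hdf5_container_roundtrip(self, tmp_path):
        cfg = sd.SimulationConfig(
            side_length=16, n_classes=2, per_class=3, snr=math.inf,
            wedge_half_angle=None, seed=1, n_neighbors_range=(0, 0),
        )
        man = sd.generate_dataset(cfg, tmp_path, container="hdf5")
        store = VolumeStore(man, tmp_path)
        vol = store.get(man["id"].iloc[0])
        assert vol.shape == (16, 16, 16) and np.isfinite(vol).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(side_length=4)
        with pytest.raises(ValueError):
            sd.SimulationConfig(snr=0.0)
        with pytest.raises(ValueError):
            sd.SimulationConfig(wedge_half_angle=95.0)
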