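"""Benchmark simulator: dynamics, rendering, acquisition and determinism."""

import numpy as np
import pandas as pd
import pytest

from fuzzpipe import AcquisitionConfig, DynamicsConfig, simulate_dataset
from fuzzpipe.simulate import (
    SimObject,
    generate_benchmark,
    render_ground_truth,
    simulate_acquisition,
    simulate_dynamics,
)


class TestDynamics:
    def test_single_object_single_frame(self):
        dyn = DynamicsConfig(n_initial=1, n_frames=1)
        frames = simulate_dynamics(dyn, (32, 64, 64), seed=3)
        assert len(frames) == 1 and len(frames[0]) == 1
        obj = frames[0][0]
        assert 1 - dyn.shell_thickness - 1e-9 <= obj.rho <= 1 + 1e-9

    def test_division_produces_two_children_with_parent_id(self):
        dyn = DynamicsConfig(n_initial=1, n_frames=6, division_rate=0.99)
        frames = simulate_dynamics(dyn, (32, 64, 64), seed=3)
        later = frames[-1]
        assert len(later) >= 2
        assert all(o.parent >= 1 or o.id == 1 for o in later)

    def test_pairwise_distances_respect_repulsion(self):
        dyn = DynamicsConfig(n_initial=50, n_frames=3)
        grid = (48, 192, 192)
        frames = simulate_dynamics(dyn, grid, seed=5)
        semi = dyn.semi_axes(grid)
        zr = dyn.radius_z_mean / dyn.radius_xy_mean
        scale = np.array([1.0, 1.0, 1.0 / zr])
        ok = total = 0
        for states in frames:
            pos = np.array([o.position(semi) for o in states]) * scale
            rad = np.array([o.radii[0] for o in states])
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            target = rad[:, None] + rad[None, :]
            iu = np.triu_indices(len(states), k=1)
            ok += int(np.sum(d[iu] >= 0.8 * target[iu]))
            total += len(iu[0])
        assert ok / total >= 0.99

    def test_deterministic_under_seed(self):
        dyn = DynamicsConfig(n_initial=10, n_frames=3, division_rate=0.1)
        a = simulate_dynamics(dyn, (32, 64, 64), seed=9)
        b = simulate_dynamics(dyn, (32, 64, 64), seed=9)
        for fa, fb in zip(a, b):
            assert [o.id for o in fa] == [o.id for o in fb]
            assert np.allclose([o.rho for o in fa], [o.rho for o in fb])


class TestRendering:
    def test_single_ellipsoid_volume_near_analytic(self):
        obj = SimObject(
            id=1, parent=0, direction=np.zeros(3), rho=0.0,
            radii=(10.0, 10.0, 3.0), birth_t=0, next_division=np.inf,
        )
        signal, labels, table = render_ground_truth([obj], (32, 64, 64))
        analytic = 4 / 3 * np.pi * 10 * 10 * 3
        assert table["volume"].iloc[0] == pytest.approx(analytic, rel=0.05)
        assert signal.max() == 1.0

    def test_empty_state_list(self):
        signal, labels, table = render_ground_truth([], (8, 8, 8))
        assert signal.sum() == 0 and labels.sum() == 0 and len(table) == 0

    def test_two_disjoint_objects_two_labels(self):
        mk = lambda i, x: SimObject(
            id=i, parent=0, direction=np.array([x, 0.0, 0.0]), rho=1.0,
            radii=(5.0, 5.0, 2.0), birth_t=0, next_division=np.inf,
        )
        _, labels, table = render_ground_truth(
            [mk(1, -1.0), mk(2, 1.0)], (16, 32, 64), semi_axes=np.array([20.0, 1.0, 1.0])
        )
        assert sorted(table["id"]) == [1, 2]
        assert not np.any((labels == 1) & (labels == 2))

    def test_centroid_inside_own_mask(self, tiny_dataset):
        labels = tiny_dataset.ground_truth.labels[0]
        for _, row in tiny_dataset.ground_truth.centroids.iterrows():
            z, y, x = int(round(row["z"])), int(round(row["y"])), int(round(row["x"]))
            assert labels[z, y, x] == row["id"]

    def test_size_statistics_match_target_distribution(self):
        dyn = DynamicsConfig(n_initial=150, n_frames=1)
        ds = simulate_dataset(dyn, AcquisitionConfig(), (64, 256, 256), seed=21)
        vols = ds.ground_truth.centroids["volume"]
        expected = 4 / 3 * np.pi * dyn.radius_xy_mean**2 * dyn.radius_z_mean
        assert vols.median() == pytest.approx(expected, rel=0.15)


class TestAcquisition:
    def test_noiseless_limit(self):
        sig = np.zeros((8, 16, 16), np.float32)
        sig[4, 8, 8] = 0.5
        cfg = AcquisitionConfig(
            attenuation=0.0, psf_sigma=(0, 0, 0), dark_current=0.02,
            photon_scale=np.inf, sigma_agn=0.0,
        )
        out = simulate_acquisition(sig, cfg, seed=0)
        assert np.allclose(out, sig + 0.02)

    def test_gaussian_noise_moment(self):
        sig = np.zeros((64, 128, 128), np.float32)
        cfg = AcquisitionConfig(
            attenuation=0.0, psf_sigma=(0, 0, 0), dark_current=0.5,
            photon_scale=np.inf, sigma_agn=0.01,
        )
        out = simulate_acquisition(sig, cfg, seed=1)
        assert np.std(out) == pytest.approx(0.01, rel=0.05)

    def test_poisson_mean_identity(self):
        sig = np.full((10, 10, 10), 0.3, np.float32)
        cfg = AcquisitionConfig(
            attenuation=0.0, psf_sigma=(0, 0, 0), dark_current=0.0,
            photon_scale=200.0, sigma_agn=0.0,
        )
        means = [simulate_acquisition(sig, cfg, seed=s).mean() for s in range(50)]
        assert np.mean(means) == pytest.approx(0.3, rel=0.01)

    def test_attenuation_direction_per_view(self):
        sig = np.ones((16, 8, 8), np.float32)
        cfg = AcquisitionConfig(
            attenuation=0.1, psf_sigma=(0, 0, 0), dark_current=0.0,
            photon_scale=np.inf, sigma_agn=0.0,
        )
        v0 = simulate_acquisition(sig, cfg, seed=0, view=0)
        v1 = simulate_acquisition(sig, cfg, seed=0, view=1)
        assert v0[0].mean() > v0[-1].mean()
        assert v1[-1].mean() > v1[0].mean()
        assert np.allclose(v0, v1[::-1])

    def test_snr_decreases_with_sigma_agn(self, tiny_dataset):
        sig = tiny_dataset.signals[0]
        snrs = []
        for s_agn in (0.001, 0.02, 0.08):
            cfg = AcquisitionConfig(sigma_agn=s_agn, photon_scale=np.inf)
            img = simulate_acquisition(sig, cfg, seed=2)
            obj = img[sig > 0.5].mean()
            bg = img[sig == 0].std()
            snrs.append(obj / bg)
        assert snrs[0] > snrs[1] > snrs[2]


class TestDatasetAndBenchmark:
    def test_dataset_deterministic_under_seed(self):
        dyn = DynamicsConfig(n_initial=8, n_frames=2)
        acq = AcquisitionConfig(views=(0, 1))
        a = simulate_dataset(dyn, acq, (16, 48, 48), seed=4)
        b = simulate_dataset(dyn, acq, (16, 48, 48), seed=4)
        for fa, fb in zip(a.images, b.images):
            for v in fa:
                assert np.array_equal(fa[v], fb[v])
        pd.testing.assert_frame_equal(a.ground_truth.centroids, b.ground_truth.centroids)

    def test_lineage_edges_connect_consecutive_frames(self, tiny_timeseries):
        lin = tiny_timeseries.ground_truth.lineage
        assert (lin["t_next"] - lin["t"] == 1).all()
        # every child id of frame t+1 exists in the centroid table
        cents = tiny_timeseries.ground_truth.centroids
        for _, row in lin.iterrows():
            assert ((cents["t"] == row["t_next"]) & (cents["id"] == row["id_next"])).any()

    def test_generate_benchmark_file_counts(self, tmp_path):
        generate_benchmark(
            "sbde4", tmp_path, seed=1,
            overrides={"dynamics": {"n_initial": 5, "n_frames": 3},
                       "grid_shape": (16, 48, 48)},
        )
        raws = sorted(tmp_path.glob("raw_t*_v*.tif"))
        labels = sorted(tmp_path.glob("labels_t*.tif"))
        assert len(raws) == 6  # 2 views x 3 frames
        assert len(labels) == 3
        assert (tmp_path / "manifest.yaml").exists()
        assert (tmp_path / "gt_lineage.csv").exists()

    def test_unknown_profile_errors(self, tmp_path):
        with pytest.raises(ValueError):
            generate_benchmark("nope", tmp_path)
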