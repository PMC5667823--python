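"""Multi-scale LoG seed detection, extrema, fusion and seed FSMDs."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from fuzzpipe import SeedDetectionConfig, TrapezoidParams, detect_seeds
from fuzzpipe.seeds import (
    candidates_to_table,
    compute_seed_fsmd,
    detect_extrema,
    filter_by_window_mean,
    fuse_redundant_seeds,
    log_scale_maximum,
)


def gaussian_blob(shape, center, sigma):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    r2 = sum(((g - c) / sigma) ** 2 for g, c in zip((zz, yy, xx), center))
    return np.exp(-r2 / 2).astype(np.float32)


class TestLogScaleMaximum:
    def test_constant_image_zero_response(self):
        cfg = SeedDetectionConfig(radius_range=(3, 6), n_scales=3)
        resp, _ = log_scale_maximum(np.full((9, 9, 9), 0.5, np.float32), cfg)
        # float32 filtering leaves a tiny residue, far below blob responses
        assert np.allclose(resp, 0.0, atol=5e-3)

    def test_blob_argmax_scale_matches_radius(self):
        # brute force over a fine sigma grid on a synthetic ball
        shape = (41, 41, 41)
        r = 6.0
        zz, yy, xx = np.meshgrid(*(np.arange(s) - 20 for s in shape), indexing="ij")
        ball = (zz**2 + yy**2 + xx**2 <= r**2).astype(np.float32)
        fine = np.linspace(1.0, 8.0, 40)
        best_sigma, best_val = None, -np.inf
        for s in fine:
            v = -(s**2) * ndimage.gaussian_laplace(ball, s)[20, 20, 20]
            if v > best_val:
                best_sigma, best_val = s, v
        # the 3-D optimum sits near r / sqrt(3)
        assert best_sigma == pytest.approx(r / np.sqrt(3), rel=0.15)
        cfg = SeedDetectionConfig(radius_range=(4, 9), n_scales=7, sigma_rule="sqrt3")
        resp, scale = log_scale_maximum(ball, cfg)
        zc, yc, xc = np.unravel_index(np.argmax(resp), resp.shape)
        assert (zc, yc, xc) == (20, 20, 20)
        sigmas = cfg.sigmas()
        step = sigmas[1] / sigmas[0]
        assert scale[20, 20, 20] == pytest.approx(best_sigma, rel=step - 1 + 0.1)

    def test_translation_invariance_two_blobs(self):
        img = gaussian_blob((15, 31, 31), (7, 8, 8), 2.5) + gaussian_blob(
            (15, 31, 31), (7, 22, 22), 2.5
        )
        cfg = SeedDetectionConfig(radius_range=(3, 6), n_scales=3)
        resp, _ = log_scale_maximum(img.astype(np.float32), cfg)
        assert resp[7, 8, 8] == pytest.approx(resp[7, 22, 22], rel=1e-3)

    def test_errors(self):
        cfg = SeedDetectionConfig()
        with pytest.raises(ValueError):
            log_scale_maximum(np.zeros((2, 5, 5)), cfg)
        bad = np.zeros((5, 5, 5))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            log_scale_maximum(bad, cfg)


def brute_force_extrema(resp, strict):
    """Exhaustive 26-neighbourhood scan oracle."""
    out = []
    nz, ny, nx = resp.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = resp[z, y, x]
                if v <= 0:
                    continue
                ok = True
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dz == dy == dx == 0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                n = resp[zz, yy, xx]
                                if (strict and n >= v) or (not strict and n > v):
                                    ok = False
                if ok:
                    out.append((z, y, x))
    return sorted(out)


class TestDetectExtrema:
    def test_plateau_detected_only_non_strict(self):
        resp = np.zeros((3, 3, 4), np.float32)
        resp[1, 1, :] = [1, 2, 2, 1]
        assert len(detect_extrema(resp, strict=True)) == 0
        non_strict = {tuple(c) for c in detect_extrema(resp, strict=False)}
        assert non_strict == {(1, 1, 1), (1, 1, 2)}

    def test_single_peak_identical_modes(self):
        resp = np.zeros((5, 5, 5), np.float32)
        resp[2, 2, 2] = 1.0
        s = detect_extrema(resp, strict=True)
        n = detect_extrema(resp, strict=False)
        assert np.array_equal(s, n) and len(s) == 1

    def test_random_volume_matches_oracle(self, rng):
        resp = rng.normal(size=(9, 9, 9)).astype(np.float32)
        for strict in (True, False):
            got = sorted(tuple(c) for c in detect_extrema(resp, strict=strict))
            assert got == brute_force_extrema(resp, strict)

    def test_non_strict_superset_of_strict(self, rng):
        resp = rng.uniform(size=(11, 11, 11)).astype(np.float32)
        s = {tuple(c) for c in detect_extrema(resp, strict=True)}
        n = {tuple(c) for c in detect_extrema(resp, strict=False)}
        assert s <= n


class TestWindowMeanFilter:
    def make_candidates(self, coords):
        c = np.array(coords)
        resp = np.ones((16, 16, 16), np.float32)
        scale = np.full((16, 16, 16), 2.0, np.float32)
        return candidates_to_table(c, resp, scale)

    def test_background_dropped_object_kept(self):
        img = np.full((16, 16, 16), 0.01, np.float32)
        img[8:12, 8:12, 8:12] = 0.8
        tab = self.make_candidates([(9, 9, 9), (2, 2, 2)])
        cfg = SeedDetectionConfig(t_wmi=0.1, radius_range=(4, 8))
        out = filter_by_window_mean(tab, img, cfg)
        assert list(out["x"]) == [9.0]
        assert out["max_intensity"].iloc[0] == pytest.approx(0.8)

    def test_zero_threshold_keeps_all(self):
        img = np.zeros((16, 16, 16), np.float32)
        tab = self.make_candidates([(1, 1, 1), (8, 8, 8)])
        cfg = SeedDetectionConfig(t_wmi=0.0)
        assert len(filter_by_window_mean(tab, img, cfg)) == 2


class TestFuseRedundantSeeds:
    def make_seeds(self, coords):
        c = np.array(coords, float)
        return pd.DataFrame(
            {
                "id": np.arange(1, len(c) + 1),
                "t": 0,
                "view": 0,
                "x": c[:, 0],
                "y": c[:, 1],
                "z": c[:, 2],
                "window_mean": 0.5,
            }
        )

    def test_close_pair_fuses_to_midpoint(self):
        out = fuse_redundant_seeds(self.make_seeds([(10, 10, 5), (11, 10, 5)]), t_dbc=5)
        assert len(out) == 1
        assert out["x"].iloc[0] == pytest.approx(10.5)

    def test_distant_pair_untouched(self):
        out = fuse_redundant_seeds(self.make_seeds([(0, 0, 0), (20, 0, 0)]), t_dbc=5)
        assert len(out) == 2

    def test_plateau_cluster_plus_outlier(self):
        # three redundant detections on one nucleus plus one distant seed
        seeds = self.make_seeds([(10, 10, 5), (11, 10, 5), (10, 11, 5), (40, 40, 10)])
        out = fuse_redundant_seeds(seeds, t_dbc=6)
        assert len(out) == 2
        # exhaustive dendrogram check: the three close points share a cluster
        from scipy.cluster.hierarchy import fcluster, linkage

        lab = fcluster(
            linkage(seeds[["x", "y", "z"]].to_numpy(), "ward"), t=6, criterion="distance"
        )
        assert lab[0] == lab[1] == lab[2] != lab[3]

    def test_fused_seed_inside_convex_hull(self, rng):
        pts = rng.uniform(0, 4, size=(6, 3))
        out = fuse_redundant_seeds(self.make_seeds(pts), t_dbc=50)
        assert len(out) == 1
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        fused = out[["x", "y", "z"]].to_numpy()[0]
        assert np.all(fused >= lo - 1e-9) and np.all(fused <= hi + 1e-9)


class TestSeedFsmd:
    def make_seed_table(self, z, wm=0.8, mi=0.9):
        return pd.DataFrame(
            {
                "id": [1], "t": [0], "view": [0],
                "x": [5.0], "y": [5.0], "z": [float(z)],
                "window_mean": [wm], "max_intensity": [mi],
            }
        )

    def test_plateau_seed_full_membership(self):
        cfg = SeedDetectionConfig(t_wmi=0.1)
        out = compute_seed_fsmd(self.make_seed_table(z=2), cfg, (32, 64, 64))
        assert out["fsmd_correct"].iloc[0] == pytest.approx(1.0)

    def test_minimum_takes_z_membership(self):
        cfg = SeedDetectionConfig(
            t_wmi=0.1, z_fuzzy=TrapezoidParams(0, 0, 10, 40)
        )
        out = compute_seed_fsmd(self.make_seed_table(z=19), cfg, (32, 64, 64))
        assert out["fsmd_correct"].iloc[0] == pytest.approx(0.7)

    def test_zero_membership_removed_by_alpha(self):
        cfg = SeedDetectionConfig(t_wmi=0.1, z_fuzzy=TrapezoidParams(0, 0, 5, 10))
        out = compute_seed_fsmd(self.make_seed_table(z=25), cfg, (32, 64, 64))
        assert len(out) == 0

    def test_mirrored_z_set_for_opposing_view(self):
        cfg = SeedDetectionConfig(t_wmi=0.1, z_fuzzy=TrapezoidParams(0, 0, 10, 40))
        near_far_view = compute_seed_fsmd(
            self.make_seed_table(z=30), cfg, (32, 64, 64), view=1
        )
        near_this_view = compute_seed_fsmd(
            self.make_seed_table(z=1), cfg, (32, 64, 64), view=1
        )
        assert near_far_view["fsmd_correct"].iloc[0] > near_this_view["fsmd_correct"].iloc[0]


class TestEndToEnd:
    def test_variant_ordering_on_simulated_image(self, tiny_dataset):
        from fuzzpipe import benchmark_seed_config, detection_scores

        img = tiny_dataset.images[0][0]
        gt = tiny_dataset.ground_truth.centroids[["x", "y", "z"]].to_numpy()
        cfg = benchmark_seed_config()
        scores = {}
        for method in ("logsm", "lognsm", "lognsm+f"):
            tab = detect_seeds(img, cfg, method=method)
            scores[method] = detection_scores(tab[["x", "y", "z"]].to_numpy(), gt, 6.0)
        assert scores["lognsm"].recall >= scores["logsm"].recall
        assert scores["lognsm+f"].f_score >= scores["logsm"].f_score
        assert scores["lognsm+f"].recall > 0.8
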