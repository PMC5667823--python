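"""Replication workflows on the simulated benchmark.

These functions regenerate benchmark data and score the pipeline
variants end to end, mirroring the validation experiments the package is
built around: seed detection (LoGSM / LoGNSM / LoGNSM+F), segmentation
(OTSUWW+U) and multiview tracking (OTSU+F+NN+U, OTSUWW+U+NN).  Problem
sizes default to a single-workstation scale: single frames with ~200
nuclei on a 256x256x64 grid and 10-frame two-view series with ~150
nuclei on a 192x192x56 grid.
"""

from __future__ import annotations

import numpy as np

from . import metrics, seeds, segment, simulate, tracking
from .pipeline import (
    benchmark_seed_config,
    detect_seeds_per_view,
    gt_lineage_graph,
    track_binary_fusion_fallback,
    track_segment_fusion,
)
from .tables import OperatorThresholds

__all__ = [
    "seed_detection_replicate",
    "segmentation_replicate",
    "multiview_tracking_replicate",
]

SINGLE_FRAME_GRID = (64, 256, 256)
TIMESERIES_GRID = (56, 192, 192)


def _single_frame_dataset(seed: int, n_objects: int, grid_shape):
    dyn = simulate.DynamicsConfig(n_initial=n_objects, n_frames=1)
    acq = simulate.AcquisitionConfig()
    return simulate.simulate_dataset(dyn, acq, grid_shape, seed=seed)


def seed_detection_replicate(
    seed: int,
    n_objects: int = 200,
    grid_shape=SINGLE_FRAME_GRID,
    methods=("logsm", "lognsm", "lognsm+f"),
) -> dict[str, metrics.DetectionScore]:
    """Detect seeds on one regenerated low-noise image and score each variant.

    Detections are matched one-to-one to ground-truth centroids within
    the smallest expected radius r_min.
    """
    ds = _single_frame_dataset(seed, n_objects, grid_shape)
    img = ds.images[0][0]
    gt = ds.ground_truth.centroids[["x", "y", "z"]].to_numpy()
    cfg = benchmark_seed_config()
    out = {}
    for method in methods:
        tab = seeds.detect_seeds(img, cfg, method=method)
        out[method] = metrics.detection_scores(
            tab[["x", "y", "z"]].to_numpy(), gt, max_dist=cfg.r_min
        )
    return out


def segmentation_replicate(
    seed: int,
    n_objects: int = 200,
    grid_shape=SINGLE_FRAME_GRID,
    method: str = "otsuww+u",
) -> tuple[metrics.SegmentationScore, np.ndarray, np.ndarray]:
    """Segment one regenerated image with the chosen variant and score it.

    Size fuzzy sets are quantile-fitted from the benchmark's own
    ground-truth region statistics, the way the reference trapezoids
    were derived from benchmark feature histograms.  Returns the score
    together with the predicted and reference label volumes.
    """
    ds = _single_frame_dataset(seed, n_objects, grid_shape)
    img = ds.images[0][0]
    seed_cfg = benchmark_seed_config()
    seed_tab = seeds.detect_seeds(img, seed_cfg, method="lognsm+f+u")
    sets = segment.size_fuzzy_sets(ds.ground_truth.centroids)
    seg_cfg = segment.SegmentationConfig(
        thresholds=OperatorThresholds(alpha=0.1, beta=0.5), sets=sets
    )
    labels, _ = segment.segment_stack(img, seed_tab, seg_cfg, method=method)
    score = metrics.segmentation_scores(labels, ds.ground_truth.labels[0])
    return score, labels, ds.ground_truth.labels[0]


def multiview_tracking_replicate(
    seed: int,
    n_objects: int = 150,
    n_frames: int = 10,
    grid_shape=TIMESERIES_GRID,
) -> dict[str, metrics.TrackingScore]:
    """Run both multiview tracking workflows on one regenerated series.

    The series has two opposing views per frame and dividing, migrating
    nuclei; both workflows share one set of per-view seed detections.
    """
    dyn = simulate.DynamicsConfig(
        n_initial=n_objects, n_frames=n_frames, division_rate=0.015
    )
    acq = simulate.AcquisitionConfig(views=(0, 1))
    ds = simulate.simulate_dataset(dyn, acq, grid_shape, seed=seed)
    seed_cfg = benchmark_seed_config()
    sets = segment.size_fuzzy_sets(ds.ground_truth.centroids)
    seg_cfg = segment.SegmentationConfig(
        thresholds=OperatorThresholds(alpha=0.1, beta=0.5), sets=sets
    )
    tr_cfg = tracking.TrackingConfig(thresholds=OperatorThresholds(alpha=0.0, beta=0.9))
    seed_tables = detect_seeds_per_view(ds, seed_cfg)
    gtg = gt_lineage_graph(ds.ground_truth)
    lin_fallback = track_binary_fusion_fallback(ds, seed_cfg, sets, tr_cfg, seed_tables)
    lin_fused = track_segment_fusion(
        ds, seed_cfg, seg_cfg, seed_cfg.r_min, tr_cfg, seed_tables
    )
    return {
        "otsu_fusion_fallback": metrics.tracking_scores(
            lin_fallback, gtg, max_dist=seed_cfg.r_min
        ),
        "otsuww_u_fusion": metrics.tracking_scores(lin_fused, gtg, max_dist=seed_cfg.r_min),
    }
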