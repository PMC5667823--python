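"""Otsu segmentation with uncertainty-guided watershed splitting.

Variants of the threshold-based nucleus segmentation:

* ``OTSU``     — global Otsu threshold, 26-connected components;
* ``OTSUWW``   — additionally splits every component containing two or
  more seed points by a seeded watershed (the non-guided baseline);
* ``OTSUWW+U`` — computes a size-feature FSMD per component from
  quantile-parameterised trapezoids (volume, width, height, depth
  combined with the minimum operator), splits *only* components flagged
  as larger than expected with FSMD below beta, re-evaluates the FSMDs,
  and finally removes low-FSMD components that are smaller than expected
  (FSMD below alpha = 0.1).

The most-deviating feature of a low-FSMD component decides whether it is
smaller or larger than expected, by comparing its value to the plateau
boundaries ``b`` and ``c`` of its trapezoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .fuzzy import FuzzySet, TNormKind, fit_trapezoid_from_quantiles
from .tables import OperatorThresholds, append_fsmd

__all__ = [
    "SegmentationConfig",
    "otsu_threshold",
    "label_components",
    "measure_regions",
    "size_fuzzy_sets",
    "compute_segment_fsmd",
    "classify_low_fsmd",
    "split_flagged_segments",
    "remove_low_fsmd_segments",
    "segment_stack",
]

STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)

SIZE_FEATURES = ("volume", "width", "height", "depth")


@dataclass
class SegmentationConfig:
    """Parameters of the uncertainty-guided segmentation operator."""

    thresholds: OperatorThresholds = field(
        default_factory=lambda: OperatorThresholds(alpha=0.1, beta=0.5)
    )
    sets: list[FuzzySet] = field(default_factory=list)
    landscape: str = "intensity"  # or "distance"
    crop_margin: int = 2
    smoothing_sigma: float = 1.0
    tnorm: TNormKind = TNormKind.MINIMUM
    removal_mode: str = "too_small"  # or "all"


def otsu_threshold(image: np.ndarray) -> np.ndarray:
    """Global Otsu threshold; foreground is the above-threshold class."""
    image = np.asarray(image)
    if np.unique(image).size < 2:
        raise ValueError("Otsu thresholding requires at least two distinct values")
    thr = threshold_otsu(image)
    return image > thr


def label_components(binary: np.ndarray) -> np.ndarray:
    """26-connected component labelling, labels dense 1..K, 0 = background."""
    labels, _ = ndimage.label(np.asarray(binary, dtype=bool), structure=STRUCTURE_26)
    return labels.astype(np.int32)


def measure_regions(labels: np.ndarray, image: np.ndarray | None = None) -> pd.DataFrame:
    """One record per label: centroid, volume and inclusive bbox extents.

    Columns: id, x, y, z (centroid in voxels), volume, width, height,
    depth, plus mean/max intensity when an intensity image is supplied.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = []
    if ids.size:
        slices = ndimage.find_objects(labels)
        ones = np.ones(labels.shape, dtype=np.float32)
        coms = ndimage.center_of_mass(ones, labels, ids)
        vols = ndimage.sum_labels(ones, labels, ids)
        if image is not None:
            means = ndimage.mean(image, labels, ids)
            maxs = ndimage.maximum(image, labels, ids)
        for k, lab in enumerate(ids):
            sl = slices[int(lab) - 1]
            row = {
                "id": int(lab),
                "x": float(coms[k][2]),
                "y": float(coms[k][1]),
                "z": float(coms[k][0]),
                "volume": float(vols[k]),
                "width": sl[2].stop - sl[2].start,
                "height": sl[1].stop - sl[1].start,
                "depth": sl[0].stop - sl[0].start,
            }
            if image is not None:
                row["mean_intensity"] = float(means[k])
                row["max_intensity"] = float(maxs[k])
            rows.append(row)
    cols = ["id", "x", "y", "z", "volume", "width", "height", "depth"]
    if image is not None:
        cols += ["mean_intensity", "max_intensity"]
    return pd.DataFrame(rows, columns=cols)


def size_fuzzy_sets(
    samples: pd.DataFrame,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
    features: tuple[str, ...] = SIZE_FEATURES,
) -> list[FuzzySet]:
    """Fit one trapezoid per size feature from reference region samples.

    Minimum/maximum become the outer breakpoints and the 5%/95% quantiles
    the plateau, so 90% of the reference range gets membership one and
    anything outside the observed range membership zero.
    """
    sets = []
    for feat in features:
        params = fit_trapezoid_from_quantiles(samples[feat].to_numpy(), lower_q, upper_q)
        sets.append(FuzzySet("correct", params, feat))
    return sets


def compute_segment_fsmd(
    records: pd.DataFrame,
    sets: list[FuzzySet],
    kind: TNormKind | str = TNormKind.MINIMUM,
) -> pd.DataFrame:
    """Append the combined size FSMD (min over per-feature memberships)."""
    return append_fsmd(records, sets, kind=kind, term="correct")


def classify_low_fsmd(record: pd.Series, sets: list[FuzzySet]) -> str:
    """Decide whether a low-FSMD record is ``too_small``, ``too_large`` or ``ok``.

    The feature deviating the most (lowest membership) is compared to the
    plateau boundaries of its trapezoid: below ``b`` means smaller than
    expected, above ``c`` larger.
    """
    worst = None
    worst_mu = np.inf
    for s in sets:
        mu = s(float(record[s.feature]))
        if mu < worst_mu:
            worst_mu = mu
            worst = s
    if worst is None or worst_mu >= 1.0:
        return "ok"
    val = float(record[worst.feature])
    if val < worst.params.b:
        return "too_small"
    if val > worst.params.c:
        return "too_large"
    return "ok"


def _watershed_split(
    labels: np.ndarray,
    image: np.ndarray,
    lab: int,
    seeds_zyx: np.ndarray,
    config: SegmentationConfig,
    next_label: int,
) -> int:
    """Split one segment in place by a seeded watershed on a cropped region.

    Returns the next free label.  The segment's voxel set is preserved
    and partitioned among the seeds; with fewer than two interior seeds
    the segment is left unchanged.
    """
    pos = np.argwhere(labels == lab)
    if len(pos) == 0:
        return next_label
    lo = pos.min(axis=0)
    hi = pos.max(axis=0) + 1
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    m = config.crop_margin
    sl = tuple(
        slice(max(0, s.start - m), min(n, s.stop + m))
        for s, n in zip(sl, labels.shape)
    )
    mask = labels[sl] == lab
    inside = []
    for z, y, x in seeds_zyx:
        zz, yy, xx = int(z) - sl[0].start, int(y) - sl[1].start, int(x) - sl[2].start
        if (
            0 <= zz < mask.shape[0]
            and 0 <= yy < mask.shape[1]
            and 0 <= xx < mask.shape[2]
            and mask[zz, yy, xx]
        ):
            inside.append((zz, yy, xx))
    if len(inside) < 2:
        return next_label
    markers = np.zeros(mask.shape, dtype=np.int32)
    for k, (zz, yy, xx) in enumerate(inside, start=1):
        markers[zz, yy, xx] = k
    if config.landscape == "distance":
        land = -ndimage.distance_transform_edt(mask)
    else:
        crop = np.asarray(image[sl], dtype=np.float32)
        if config.smoothing_sigma > 0:
            crop = ndimage.gaussian_filter(crop, config.smoothing_sigma)
        land = -crop
    parts = watershed(land, markers=markers, mask=mask)
    region = labels[sl]
    for k in range(1, len(inside) + 1):
        region[parts == k] = next_label
        next_label += 1
    # voxels of the mask missed by the watershed stay with the first part
    region[mask & (parts == 0)] = next_label - len(inside)
    return next_label


def split_flagged_segments(
    labels: np.ndarray,
    image: np.ndarray,
    seeds: pd.DataFrame,
    records: pd.DataFrame,
    config: SegmentationConfig,
    guided: bool = True,
) -> tuple[np.ndarray, int]:
    """Split under-segmented components by a seeded watershed.

    Guided mode (OTSUWW+U) crops and splits only components flagged as
    larger than expected with FSMD below beta; the non-guided baseline
    (OTSUWW) processes every component containing two or more seeds.
    Returns the new label volume (labels re-densified) and the number of
    watershed invocations.
    """
    labels = np.asarray(labels).copy()
    if guided and "fsmd_correct" not in records.columns:
        raise KeyError("guided splitting requires FSMD values on the records")
    if guided:
        flagged = []
        for _, rec in records.iterrows():
            if rec["fsmd_correct"] < config.thresholds.beta:
                if classify_low_fsmd(rec, config.sets) == "too_large":
                    flagged.append(int(rec["id"]))
    else:
        flagged = [int(i) for i in records["id"]]
    seeds_zyx = seeds[["z", "y", "x"]].to_numpy(dtype=float)
    next_label = int(labels.max()) + 1
    n_invocations = 0
    for lab in flagged:
        before = next_label
        next_label = _watershed_split(labels, image, lab, seeds_zyx, config, next_label)
        if not guided and next_label == before:
            continue  # fewer than 2 seeds: not an invocation that split
        if guided or next_label > before:
            n_invocations += 1
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32), n_invocations


def remove_low_fsmd_segments(
    labels: np.ndarray,
    records: pd.DataFrame,
    config: SegmentationConfig,
) -> np.ndarray:
    """Clear low-FSMD segments to background and re-densify the labels.

    Default mode removes components with FSMD below alpha that are
    *smaller* than expected (noise specks, background fragments); larger-
    than-expected components that could not be split are kept so that
    downstream operators can still fall back on their seeds.  Mode
    ``"all"`` removes every record below alpha.
    """
    labels = np.asarray(labels).copy()
    if "fsmd_correct" not in records.columns:
        raise KeyError("records must carry FSMD values")
    doomed = []
    for _, rec in records.iterrows():
        if rec["fsmd_correct"] >= config.thresholds.alpha:
            continue
        if config.removal_mode == "all" or (
            classify_low_fsmd(rec, config.sets) == "too_small"
        ):
            doomed.append(int(rec["id"]))
    if doomed:
        mask = np.isin(labels, doomed)
        labels[mask] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_stack(
    image: np.ndarray,
    seeds: pd.DataFrame | None = None,
    config: SegmentationConfig | None = None,
    method: str = "otsuww+u",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Run a segmentation variant end to end on one stack.

    ``method``: ``otsu`` (threshold + components), ``otsuww`` (watershed
    split of every multi-seed component) or ``otsuww+u`` (FSMD-guided
    splitting plus low-FSMD removal).  Returns the final label volume
    and the region table with FSMD values (when fuzzy sets are
    configured).
    """
    config = config or SegmentationConfig()
    method = method.lower()
    if method not in ("otsu", "otsuww", "otsuww+u"):
        raise ValueError(f"unknown segmentation method {method!r}")
    labels = label_components(otsu_threshold(image))
    records = measure_regions(labels, image)
    if config.sets:
        records = compute_segment_fsmd(records, config.sets, config.tnorm)
    if method == "otsu":
        return labels, records
    if seeds is None or len(seeds) == 0:
        return labels, records
    if method == "otsuww":
        labels, _ = split_flagged_segments(labels, image, seeds, records, config, guided=False)
        records = measure_regions(labels, image)
        if config.sets:
            records = compute_segment_fsmd(records, config.sets, config.tnorm)
        return labels, records
    # otsuww+u
    if not config.sets:
        raise ValueError("otsuww+u requires size fuzzy sets in the config")
    labels, _ = split_flagged_segments(labels, image, seeds, records, config, guided=True)
    records = measure_regions(labels, image)
    records = compute_segment_fsmd(records, config.sets, config.tnorm)
    labels = remove_low_fsmd_segments(labels, records, config)
    records = measure_regions(labels, image)
    records = compute_segment_fsmd(records, config.sets, config.tnorm)
    return labels, records
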