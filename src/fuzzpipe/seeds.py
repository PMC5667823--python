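"""Multi-scale LoG seed detection with fuzzy uncertainty estimation.

The detector filters a 3D stack with a bank of scale-normalised
Laplacian-of-Gaussian kernels tuned to the expected nucleus radius
range, forms the per-voxel maximum projection over scales, and extracts
local extrema.  Variants:

* ``LoGSM``    — strict 26-neighbourhood maxima only;
* ``LoGNSM``   — non-strict maxima (``>=``), which also captures intensity
  plateaus of elongated or saturated nuclei, plus a window-mean-intensity
  threshold ``t_wmi`` against background detections;
* ``LoGNSM+F`` — additionally fuses redundant detections of one object by
  Ward-linkage clustering with a distance cutoff ``t_dbc`` (set to the
  smallest expected radius) and feature-vector averaging;
* ``LoGNSM+F+U`` — additionally estimates per-seed FSMD values from the
  window mean intensity, the maximum seed intensity and the z position
  (image quality decreases away from the detection objective), combined
  with the minimum operator and forward-filtered at alpha = 0.0001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from skimage.filters import threshold_otsu

from .fuzzy import FuzzySet, TNormKind, TrapezoidParams
from .tables import OperatorThresholds, append_fsmd, filter_forward

__all__ = [
    "SeedDetectionConfig",
    "log_scale_maximum",
    "detect_extrema",
    "candidates_to_table",
    "filter_by_window_mean",
    "fuse_redundant_seeds",
    "compute_seed_fsmd",
    "detect_seeds",
]

SEED_COLUMNS = [
    "id", "t", "view", "x", "y", "z",
    "scale", "log_response", "max_intensity", "window_mean",
]


@dataclass
class SeedDetectionConfig:
    """Parameters of the LoG seed detector.

    ``radius_range`` is the expected in-plane object radius range in
    voxels; scales are sampled geometrically between the two and mapped
    to sigma via ``sigma_rule`` (``"sqrt3"``: sigma = r / sqrt(3), the
    response maximum of the 3-D LoG for a ball of radius r; ``"half"``:
    sigma = r / 2).  ``sigma_factors`` scale sigma per (z, y, x) axis for
    anisotropic data.  ``t_wmi`` is the window-mean-intensity threshold;
    ``None`` selects an automatic Otsu split of the candidate window
    means (an extension beyond manual tuning).
    """

    radius_range: tuple[float, float] = (6.0, 12.0)
    n_scales: int = 5
    sigma_rule: str = "sqrt3"
    sigma_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x)
    strict: bool = False
    t_wmi: float | None = 0.1
    window_halfwidth: int | None = None  # default round(r_min / 2)
    t_dbc: float | None = None  # default r_min
    alpha: float = 0.0001
    tnorm: TNormKind = TNormKind.MINIMUM
    window_mean_fuzzy: TrapezoidParams | None = None
    max_intensity_fuzzy: TrapezoidParams | None = None
    z_fuzzy: TrapezoidParams | None = None

    @property
    def r_min(self) -> float:
        return self.radius_range[0]

    def sigmas(self) -> np.ndarray:
        r_min, r_max = self.radius_range
        if not (0 < r_min <= r_max):
            raise ValueError("invalid radius range")
        radii = np.geomspace(r_min, r_max, self.n_scales)
        if self.sigma_rule == "sqrt3":
            return radii / math.sqrt(3.0)
        if self.sigma_rule == "half":
            return radii / 2.0
        raise ValueError(f"unknown sigma rule {self.sigma_rule!r}")

    def window(self) -> int:
        hw = self.window_halfwidth
        if hw is None:
            hw = max(1, round(self.r_min / 2))
        return int(hw)


def log_scale_maximum(
    image: np.ndarray, config: SeedDetectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Scale-normalised negated-LoG response, maximum-projected over scales.

    Returns the per-voxel maximum response and the argmax sigma (the
    in-plane sigma before per-axis anisotropy factors).  Responses are
    multiplied by sigma^2 so maxima are comparable across scales; the
    sign is flipped so bright blobs give positive responses.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or min(image.shape) < 3:
        raise ValueError("need a 3D image with at least 3 voxels per axis")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    sigmas = config.sigmas()
    if sigmas.size == 0:
        raise ValueError("empty scale set")
    fz, fy, fx = config.sigma_factors
    response = np.full(image.shape, -np.inf, dtype=np.float32)
    scale = np.zeros(image.shape, dtype=np.float32)
    for s in sigmas:
        r = -(s**2) * ndimage.gaussian_laplace(image, sigma=(s * fz, s * fy, s * fx))
        better = r > response
        response[better] = r[better]
        scale[better] = s
    return response, scale


def detect_extrema(response: np.ndarray, strict: bool = False) -> np.ndarray:
    """Voxel coordinates (N, 3) as (z, y, x) of positive local maxima.

    ``strict``: voxel greater than all 26 neighbours; non-strict: greater
    or equal (captures plateaus).  Non-positive responses are never
    candidates — the LoG of background is zero up to noise, so only
    bright-blob responses qualify.  The non-strict set is a superset of
    the strict set.
    """
    response = np.asarray(response, dtype=np.float32)
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neighbour_max = ndimage.maximum_filter(
        response, footprint=footprint, mode="constant", cval=-np.inf
    )
    if strict:
        mask = response > neighbour_max
    else:
        mask = response >= neighbour_max
    mask &= response > 0
    return np.argwhere(mask)


def candidates_to_table(
    candidates: np.ndarray,
    response: np.ndarray,
    scale: np.ndarray,
    t: int = 0,
    view: int = 0,
) -> pd.DataFrame:
    """Build a seed table (x, y, z voxel coordinates) from candidate voxels."""
    rows = {
        "id": np.arange(1, len(candidates) + 1),
        "t": t,
        "view": view,
        "x": candidates[:, 2].astype(float) if len(candidates) else [],
        "y": candidates[:, 1].astype(float) if len(candidates) else [],
        "z": candidates[:, 0].astype(float) if len(candidates) else [],
        "scale": scale[tuple(candidates.T)] if len(candidates) else [],
        "log_response": response[tuple(candidates.T)] if len(candidates) else [],
    }
    return pd.DataFrame(rows)


def filter_by_window_mean(
    seeds: pd.DataFrame, image: np.ndarray, config: SeedDetectionConfig
) -> pd.DataFrame:
    """Drop candidates whose surrounding window mean falls below ``t_wmi``.

    Also records the ``window_mean`` and ``max_intensity`` features used
    later for the uncertainty estimate.  Windows are cubes of half-width
    ``round(r_min / 2)`` clipped at the image border.  ``t_wmi = None``
    derives the threshold automatically by an Otsu split of the
    candidate window-mean distribution.
    """
    image = np.asarray(image, dtype=np.float32)
    hw = config.window()
    wm = np.empty(len(seeds))
    mx = np.empty(len(seeds))
    zs = seeds["z"].to_numpy().astype(int)
    ys = seeds["y"].to_numpy().astype(int)
    xs = seeds["x"].to_numpy().astype(int)
    nz, ny, nx = image.shape
    for k in range(len(seeds)):
        z0, z1 = max(0, zs[k] - hw), min(nz, zs[k] + hw + 1)
        y0, y1 = max(0, ys[k] - hw), min(ny, ys[k] + hw + 1)
        x0, x1 = max(0, xs[k] - hw), min(nx, xs[k] + hw + 1)
        win = image[z0:z1, y0:y1, x0:x1]
        wm[k] = win.mean()
        mx[k] = win.max()
    out = seeds.copy()
    out["window_mean"] = wm
    out["max_intensity"] = mx
    t_wmi = config.t_wmi
    if t_wmi is None:
        t_wmi = float(threshold_otsu(wm)) if len(np.unique(wm)) > 1 else 0.0
    return out.loc[out["window_mean"] >= t_wmi].reset_index(drop=True)


def fuse_redundant_seeds(seeds: pd.DataFrame, t_dbc: float) -> pd.DataFrame:
    """Merge redundant detections of one object by Ward-linkage clustering.

    The hierarchical cluster tree over (x, y, z) is cut at linkage
    distance ``t_dbc`` (chosen as the smallest expected object radius, so
    close redundant detections fuse while neighbouring objects stay
    apart); each cluster is replaced by the mean of its members' feature
    vectors.
    """
    if t_dbc <= 0:
        raise ValueError("t_dbc must be positive")
    if len(seeds) == 0:
        return seeds.copy()
    coords = seeds[["x", "y", "z"]].to_numpy(dtype=float)
    if len(seeds) == 1:
        labels = np.array([1])
    else:
        tree = linkage(coords, method="ward")
        labels = fcluster(tree, t=t_dbc, criterion="distance")
    num_cols = [
        c for c in seeds.columns
        if c not in ("id", "t", "view") and pd.api.types.is_numeric_dtype(seeds[c])
    ]
    grouped = seeds.groupby(labels, sort=True)
    fused = grouped[num_cols].mean().reset_index(drop=True)
    fused.insert(0, "view", grouped["view"].first().to_numpy())
    fused.insert(0, "t", grouped["t"].first().to_numpy())
    fused.insert(0, "id", np.arange(1, len(fused) + 1))
    return fused


def _default_fuzzy_sets(config: SeedDetectionConfig, image_shape) -> list[FuzzySet]:
    nz = image_shape[0]
    t_wmi = min(1.0, config.t_wmi if config.t_wmi is not None else 0.0)
    # intensity sets rise to a plateau: values at/above ~t_wmi are certain
    wm = config.window_mean_fuzzy or TrapezoidParams(0.5 * t_wmi, t_wmi, 1.0, 1.0)
    mi = config.max_intensity_fuzzy or TrapezoidParams(
        t_wmi, min(1.0, 1.5 * t_wmi), 1.0, 1.0
    )
    # quality decays with distance from the detection objective at z = 0;
    # membership falls from the plateau but stays > 0 inside the stack
    zf = config.z_fuzzy or TrapezoidParams(0.0, 0.0, 0.5 * nz, 1.5 * nz)
    return [
        FuzzySet("correct", wm, "window_mean"),
        FuzzySet("correct", mi, "max_intensity"),
        FuzzySet("correct", zf, "z"),
    ]


def compute_seed_fsmd(
    seeds: pd.DataFrame,
    config: SeedDetectionConfig,
    image_shape: tuple[int, int, int],
    view: int = 0,
) -> pd.DataFrame:
    """Append the seed FSMD (min over the three feature memberships).

    The z fuzzy set is mirrored for the opposing view (objective at the
    far z face).  Rows are then forward-filtered at
    alpha = 0.0001 — slightly above zero, so only certain false positives
    with membership exactly 0 are dropped.
    """
    sets = _default_fuzzy_sets(config, image_shape)
    if view == 1:
        zf = sets[2].params
        nz = image_shape[0]
        mirrored = TrapezoidParams(nz - 1 - zf.d, nz - 1 - zf.c, nz - 1 - zf.b, nz - 1 - zf.a)
        sets[2] = FuzzySet("correct", mirrored, "z")
    out = append_fsmd(seeds, sets, kind=config.tnorm, term="correct")
    return filter_forward(out, "fsmd_correct", OperatorThresholds(alpha=config.alpha))


def detect_seeds(
    image: np.ndarray,
    config: SeedDetectionConfig | None = None,
    method: str = "lognsm+f+u",
    t: int = 0,
    view: int = 0,
) -> pd.DataFrame:
    """Run a full seed-detection variant on one stack.

    ``method`` is one of ``logsm``, ``lognsm``, ``lognsm+f``,
    ``lognsm+f+u`` (case-insensitive).  All variants apply the
    window-mean intensity threshold; ``+f`` adds Ward fusion of redundant
    seeds; ``+u`` adds the FSMD estimate and the alpha filter.
    """
    config = config or SeedDetectionConfig()
    method = method.lower()
    if method not in ("logsm", "lognsm", "lognsm+f", "lognsm+f+u"):
        raise ValueError(f"unknown seed detection method {method!r}")
    strict = method == "logsm"
    response, scale = log_scale_maximum(image, config)
    cands = detect_extrema(response, strict=strict)
    table = candidates_to_table(cands, response, scale, t=t, view=view)
    table = filter_by_window_mean(table, image, config)
    if method in ("lognsm+f", "lognsm+f+u"):
        t_dbc = config.t_dbc if config.t_dbc is not None else config.r_min
        table = fuse_redundant_seeds(table, t_dbc)
        table["t"] = t
        table["view"] = view
    if method == "lognsm+f+u":
        table = compute_seed_fsmd(table, config, image.shape, view=view)
    return table
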