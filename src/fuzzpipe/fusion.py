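"""Multiview fusion of two opposing-view results on a common grid.

Opposing light-sheet views of one specimen see the same objects with
complementary quality: each view degrades with distance from its own
detection objective.  Two fusion strategies are provided:

* binary maximum fusion — the voxelwise OR of the per-view foreground
  masks (used before connected-component labelling);
* segment-based fusion — match segments of the two views by centroid
  proximity and keep, per matched pair, the record with the higher FSMD.
  The matching is greedy by ascending centroid distance and one-to-one;
  this rule is a reconstruction of the segment-based approach and is
  deliberately simple.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["fuse_binary_max", "fuse_segments_fsmd", "greedy_match"]


def fuse_binary_max(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Voxelwise maximum (OR for binary masks) of two registered volumes."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.maximum(a, b)


def greedy_match(
    coords_a: np.ndarray, coords_b: np.ndarray, max_dist: float
) -> list[tuple[int, int, float]]:
    """One-to-one matching by ascending pairwise distance within ``max_dist``.

    Returns (index_a, index_b, distance) triples.  Deterministic: ties
    resolve by lowest (a, b) index pair.
    """
    if len(coords_a) == 0 or len(coords_b) == 0:
        return []
    d = cdist(np.asarray(coords_a, float), np.asarray(coords_b, float))
    pairs = [
        (d[i, j], i, j)
        for i in range(d.shape[0])
        for j in range(d.shape[1])
        if d[i, j] <= max_dist
    ]
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for dist, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, float(dist)))
    return out


def fuse_segments_fsmd(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    match_radius: float,
    fsmd_col: str = "fsmd_correct",
) -> pd.DataFrame:
    """Fuse two per-view region tables into one object set.

    Segments whose centroids lie within ``match_radius`` are matched
    one-to-one (greedy by ascending distance); for each matched pair the
    record with the higher FSMD wins (ties prefer view A).  Unmatched
    records are kept as-is.  The output records provenance in ``view``
    and ``source_id`` columns and is re-indexed with fresh ids.
    """
    a = records_a.reset_index(drop=True)
    b = records_b.reset_index(drop=True)
    for tbl, name in ((a, "A"), (b, "B")):
        if len(tbl) and fsmd_col not in tbl.columns:
            raise KeyError(f"view {name} records lack FSMD column {fsmd_col!r}")
    matches = greedy_match(
        a[["x", "y", "z"]].to_numpy(float) if len(a) else np.empty((0, 3)),
        b[["x", "y", "z"]].to_numpy(float) if len(b) else np.empty((0, 3)),
        match_radius,
    )
    matched_a = {i for i, _, _ in matches}
    matched_b = {j for _, j, _ in matches}
    rows = []
    for i, j, _ in matches:
        ra, rb = a.iloc[i], b.iloc[j]
        winner, view = (ra, 0) if ra[fsmd_col] >= rb[fsmd_col] else (rb, 1)
        row = winner.to_dict()
        row["view"] = view
        row["source_id"] = int(winner["id"])
        rows.append(row)
    for i in range(len(a)):
        if i not in matched_a:
            row = a.iloc[i].to_dict()
            row["view"] = 0
            row["source_id"] = int(a.iloc[i]["id"])
            rows.append(row)
    for j in range(len(b)):
        if j not in matched_b:
            row = b.iloc[j].to_dict()
            row["view"] = 1
            row["source_id"] = int(b.iloc[j]["id"])
            rows.append(row)
    fused = pd.DataFrame(rows)
    if len(fused):
        fused["id"] = np.arange(1, len(fused) + 1)
    return fused.reset_index(drop=True)
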