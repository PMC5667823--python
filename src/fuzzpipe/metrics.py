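"""Detection, segmentation and tracking performance measures.

* Detection: greedy one-to-one centroid matching within a radius;
  TP/FP/FN, recall, precision, F-score and mean matched distance.
* Segmentation: Rand index (RI) and Jaccard index (JI) over
  foreground-restricted voxel pairs / matched objects, normalised sum of
  distances (NSD) and Hausdorff metric (HM) over matched object
  boundaries, plus topology errors (split, merged, added, missing) via
  majority-overlap mapping.  Following the convention of the reference
  scores, split and added objects count as false positives, merged and
  missing ones as false negatives.
* Tracking: edge-level TP/FP/FN, redundant/missing/merged counts and the
  TRA measure TRA = 1 - min(AOGM, AOGM0)/AOGM0, where AOGM is the
  weighted cost of editing the predicted acyclic oriented graph into the
  reference and AOGM0 the cost of building the reference from scratch
  (weights follow the cell-tracking-challenge formulation and are
  configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .fusion import greedy_match
from .tracking import LineageGraph

__all__ = [
    "DetectionScore",
    "SegmentationScore",
    "TrackingScore",
    "AOGMWeights",
    "match_detections",
    "detection_scores",
    "segmentation_scores",
    "tracking_scores",
]


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f


@dataclass(frozen=True)
class DetectionScore:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f_score: float
    mean_distance: float


@dataclass(frozen=True)
class SegmentationScore:
    ri: float
    ji: float
    nsd: float
    hm: float
    split: int
    merged: int
    added: int
    missing: int
    tp: int
    recall: float
    precision: float
    f_score: float


@dataclass(frozen=True)
class AOGMWeights:
    """Edit-operation weights of the AOGM tracking cost."""

    ns: float = 5.0  # vertex split (one pred marker covers several references)
    fn: float = 10.0  # missing vertex
    fp: float = 1.0  # spurious vertex
    ed: float = 1.0  # redundant edge deletion
    ea: float = 1.5  # missing edge addition
    ec: float = 1.0  # edge semantics change


@dataclass(frozen=True)
class TrackingScore:
    tp: int
    fp: int
    fn: int
    redundant: int
    missing: int
    merged: int
    recall: float
    precision: float
    f_score: float
    tra: float


def match_detections(
    pred: np.ndarray, gt: np.ndarray, max_dist: float
) -> list[tuple[int, int, float]]:
    """Greedy ascending-distance one-to-one matching of two point sets."""
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    return greedy_match(np.atleast_2d(pred), np.atleast_2d(gt), max_dist)


def detection_scores(
    pred: np.ndarray, gt: np.ndarray, max_dist: float
) -> DetectionScore:
    """Score predicted centroids against ground truth."""
    pred = np.asarray(pred, float).reshape(-1, 3)
    gt = np.asarray(gt, float).reshape(-1, 3)
    matches = match_detections(pred, gt, max_dist) if len(pred) and len(gt) else []
    tp = len(matches)
    fp = len(pred) - tp
    fn = len(gt) - tp
    precision, recall, f = _prf(tp, fp, fn)
    mean_d = float(np.mean([m[2] for m in matches])) if matches else 0.0
    return DetectionScore(tp, fp, fn, recall, precision, f, mean_d)


# ---------------------------------------------------------------------------
# segmentation


def _rand_index_foreground(
    pred: np.ndarray, gt: np.ndarray, max_pairs: int, rng: np.random.Generator
) -> float:
    """Rand index over voxel pairs drawn from the foreground union.

    Exact all-pairs evaluation when the pair count fits the budget;
    otherwise a uniform subsample of pairs.
    """
    idx = np.flatnonzero((pred.ravel() > 0) | (gt.ravel() > 0))
    n = idx.size
    if n < 2:
        return 1.0
    p = pred.ravel()[idx].astype(np.int64)
    g = gt.ravel()[idx].astype(np.int64)
    n_pairs = n * (n - 1) // 2
    if n_pairs <= max_pairs:
        same_p = p[:, None] == p[None, :]
        same_g = g[:, None] == g[None, :]
        iu = np.triu_indices(n, k=1)
        return float(np.mean(same_p[iu] == same_g[iu]))
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n, size=max_pairs)
    keep = i != j
    i, j = i[keep], j[keep]
    return float(np.mean((p[i] == p[j]) == (g[i] == g[j])))


def _object_maps(pred: np.ndarray, gt: np.ndarray):
    """Overlap bookkeeping between predicted and reference labels."""
    pred_ids = np.unique(pred)
    pred_ids = pred_ids[pred_ids > 0]
    gt_ids = np.unique(gt)
    gt_ids = gt_ids[gt_ids > 0]
    # joint histogram of (pred, gt) label pairs over the union foreground
    mask = (pred > 0) | (gt > 0)
    pv = pred[mask].astype(np.int64)
    gv = gt[mask].astype(np.int64)
    pair_index = pv * (int(gt.max()) + 1) + gv
    counts = pd.Series(pair_index).value_counts()
    overlap: dict[tuple[int, int], int] = {}
    for key, cnt in counts.items():
        overlap[(int(key) // (int(gt.max()) + 1), int(key) % (int(gt.max()) + 1))] = int(cnt)
    pc = np.bincount(pv)
    gc = np.bincount(gv)
    pred_sizes = {int(i): int(pc[int(i)]) for i in pred_ids}
    gt_sizes = {int(i): int(gc[int(i)]) for i in gt_ids}
    return pred_ids, gt_ids, overlap, pred_sizes, gt_sizes


def segmentation_scores(
    pred: np.ndarray,
    gt: np.ndarray,
    max_ri_pairs: int = 100_000,
    seed: int = 0,
) -> SegmentationScore:
    """Compare a predicted label volume against the reference.

    Topology mapping: a predicted object with more than half of its
    voxels on reference background is *added*; each reference object is
    assigned the predicted label covering the plurality of its voxels
    (or counts as *missing* when background covers the majority);
    *merged* counts the extra reference objects absorbed into one
    prediction, *split* the extra predictions majority-inside one
    reference object.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("label volumes must share one shape")
    rng = np.random.default_rng(seed)
    ri = _rand_index_foreground(pred, gt, max_ri_pairs, rng)

    pred_ids, gt_ids, overlap, pred_sizes, gt_sizes = _object_maps(pred, gt)

    # added: predicted object mostly on reference background
    added_ids = set()
    for p in pred_ids:
        p = int(p)
        on_fg = sum(c for (pp, g), c in overlap.items() if pp == p and g > 0)
        if on_fg <= 0.5 * pred_sizes[p]:
            added_ids.add(p)

    # reference -> predicted assignment by plurality coverage
    assign: dict[int, int] = {}
    missing = 0
    for g in gt_ids:
        g = int(g)
        cover = {int(pp): c for (pp, gg), c in overlap.items() if gg == g and pp > 0}
        covered = sum(cover.values())
        if covered < 0.5 * gt_sizes[g] or not cover:
            missing += 1
            continue
        assign[g] = max(sorted(cover), key=lambda p: cover[p])

    # merged: one prediction absorbing several references
    merged = 0
    by_pred: dict[int, list[int]] = {}
    for g, p in assign.items():
        by_pred.setdefault(p, []).append(g)
    for p, gs in by_pred.items():
        merged += max(0, len(gs) - 1)

    # split: several predictions majority-inside one reference
    split = 0
    inside_counts: dict[int, int] = {}
    for p in pred_ids:
        p = int(p)
        if p in added_ids:
            continue
        cover = {int(gg): c for (pp, gg), c in overlap.items() if pp == p and gg > 0}
        if not cover:
            continue
        host = max(sorted(cover), key=lambda g: cover[g])
        if cover[host] > 0.5 * pred_sizes[p]:
            inside_counts[host] = inside_counts.get(host, 0) + 1
    for g, k in inside_counts.items():
        split += max(0, k - 1)

    tp = max(0, len(gt_ids) - missing - merged)
    fp = split + len(added_ids)
    fn = merged + missing
    precision, recall, f = _prf(tp, fp, fn)

    # boundary/overlap metrics over matched (reference, assigned) pairs,
    # evaluated on joint bounding boxes to keep the distance transforms local
    gt_slices = ndimage.find_objects(gt)
    jis, nsds, hms = [], [], []
    for g, p in assign.items():
        sg = gt_slices[g - 1]
        # window: reference bbox padded by its own extent, so a grossly
        # over-sized prediction is judged locally around the reference
        sl = tuple(
            slice(max(0, a.start - max(3, a.stop - a.start)),
                  min(n, a.stop + max(3, a.stop - a.start)))
            for a, n in zip(sg, gt.shape)
        )
        gm = gt[sl] == g
        pm = pred[sl] == p
        inter = int(np.sum(gm & pm))
        union = int(np.sum(gm | pm))
        jis.append(inter / union if union else 0.0)
        # distances measured from the reference object's boundary
        dist_out = ndimage.distance_transform_edt(~gm)
        dist_in = ndimage.distance_transform_edt(gm)
        dist = np.maximum(dist_out, dist_in - 1)  # 0 on the boundary shell
        sym_diff = gm ^ pm
        both = gm | pm
        denom = float(dist[both].sum())
        nsds.append(float(dist[sym_diff].sum()) / denom if denom > 0 else 0.0)
        hms.append(float(dist[sym_diff].max()) if sym_diff.any() else 0.0)
    ji = float(np.mean(jis)) if jis else 0.0
    nsd = float(np.mean(nsds)) if nsds else 0.0
    hm = float(np.mean(hms)) if hms else 0.0

    return SegmentationScore(
        ri=ri, ji=ji, nsd=nsd, hm=hm,
        split=split, merged=merged, added=len(added_ids), missing=missing,
        tp=tp, recall=recall, precision=precision, f_score=f,
    )


# ---------------------------------------------------------------------------
# tracking


def _graph_coords(g: nx.DiGraph, t: int) -> tuple[list, np.ndarray]:
    nodes = sorted(n for n in g.nodes if n[0] == t)
    coords = np.array(
        [[g.nodes[n]["x"], g.nodes[n]["y"], g.nodes[n]["z"]] for n in nodes]
    ).reshape(-1, 3)
    return nodes, coords


def tracking_scores(
    pred: LineageGraph,
    gt: LineageGraph,
    max_dist: float,
    weights: AOGMWeights | None = None,
) -> TrackingScore:
    """Score a predicted lineage graph against the reference lineage.

    Reference nodes are assigned per frame to their nearest predicted
    node within ``max_dist`` (many references may share one prediction —
    a merged detection).  Edge true positives are predicted edges whose
    endpoints carry a matching reference edge.  The AOGM cost charges
    vertex splits for merged detections, missing/spurious vertices and
    missing/redundant edges; AOGM0 is the cost of building the reference
    from an empty graph (all vertices and edges missing).
    """
    weights = weights or AOGMWeights()
    gp = pred.graph
    gg = gt.graph
    frames = sorted({n[0] for n in gg.nodes} | {n[0] for n in gp.nodes})

    gt_to_pred: dict[tuple[int, int], tuple[int, int]] = {}
    matched_pred: set[tuple[int, int]] = set()
    for t in frames:
        gnodes, gcoords = _graph_coords(gg, t)
        pnodes, pcoords = _graph_coords(gp, t)
        if not gnodes or not pnodes:
            continue
        d = np.linalg.norm(gcoords[:, None, :] - pcoords[None, :, :], axis=2)
        for gi, gnode in enumerate(gnodes):
            j = int(np.argmin(d[gi]))
            if d[gi, j] <= max_dist:
                gt_to_pred[gnode] = pnodes[j]
                matched_pred.add(pnodes[j])

    # vertex statistics
    n_gt_nodes = gg.number_of_nodes()
    fn_nodes = n_gt_nodes - len(gt_to_pred)
    fp_nodes = gp.number_of_nodes() - len(matched_pred)
    pred_hits: dict[tuple[int, int], int] = {}
    for p in gt_to_pred.values():
        pred_hits[p] = pred_hits.get(p, 0) + 1
    ns_ops = sum(k - 1 for k in pred_hits.values() if k > 1)
    merged_objects = sum(1 for k in pred_hits.values() if k > 1)

    # edge statistics: a reference edge is recovered if both endpoints map
    # to predicted nodes joined by a predicted edge
    recovered_gt_edges = set()
    tp_pred_edges = set()
    for u, v in gg.edges:
        pu = gt_to_pred.get(u)
        pv = gt_to_pred.get(v)
        if pu is not None and pv is not None and gp.has_edge(pu, pv):
            recovered_gt_edges.add((u, v))
            tp_pred_edges.add((pu, pv))
    missing_edges = gg.number_of_edges() - len(recovered_gt_edges)
    redundant_edges = gp.number_of_edges() - len(tp_pred_edges)

    tp = len(tp_pred_edges)
    fp = redundant_edges
    fn = missing_edges
    precision, recall, f = _prf(tp, fp, fn)

    aogm = (
        weights.ns * ns_ops
        + weights.fn * fn_nodes
        + weights.fp * fp_nodes
        + weights.ed * redundant_edges
        + weights.ea * missing_edges
    )
    aogm0 = weights.fn * n_gt_nodes + weights.ea * gg.number_of_edges()
    tra = 1.0 - min(aogm, aogm0) / aogm0 if aogm0 > 0 else 1.0

    return TrackingScore(
        tp=tp, fp=fp, fn=fn,
        redundant=redundant_edges, missing=missing_edges, merged=merged_objects,
        recall=recall, precision=precision, f_score=f, tra=tra,
    )
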