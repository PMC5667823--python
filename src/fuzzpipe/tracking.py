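"""Nearest-neighbour tracking with an uncertainty-aware seed fallback.

Every object in frame t is linked to the spatially closest object in
frame t+1; many-to-one links are allowed (they surface as "merged"
tracking errors downstream, by design).  The uncertainty-aware variant
inspects the segment FSMD values before linking: a segment whose
combined FSMD falls below beta (default 0.9) is considered unreliable —
typically an under-segmentation that merged several nuclei — and is
replaced, as a tracking node, by the seed points its mask contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .tables import OperatorThresholds

__all__ = [
    "TrackingConfig",
    "LineageGraph",
    "link_nearest_neighbor",
    "build_tracking_nodes",
    "link_frames",
    "link_with_seed_fallback",
    "assemble_tracks",
]


@dataclass
class TrackingConfig:
    """Thresholds and geometry of the tracking operator.

    ``thresholds.beta`` is the FSMD level below which a segment is
    tracked via its contained seeds instead of its own centroid;
    ``thresholds.alpha = 0`` reports all results.  ``spacing`` converts
    voxel coordinates (x, y, z) to physical units for the distance;
    ``max_link_distance`` optionally suppresses implausibly long links.
    """

    thresholds: OperatorThresholds = field(
        default_factory=lambda: OperatorThresholds(alpha=0.0, beta=0.9)
    )
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (x, y, z)
    max_link_distance: float | None = None


@dataclass
class LineageGraph:
    """Directed lineage: nodes are (t, node id), edges link t to t+1."""

    graph: nx.DiGraph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_at(self, t: int) -> list[tuple[int, int]]:
        return sorted(n for n in self.graph.nodes if n[0] == t)

    def frames(self) -> list[int]:
        return sorted({n[0] for n in self.graph.nodes})

    @property
    def merge_events(self) -> list[tuple[int, int]]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) >= 2)


def _coords(frame: pd.DataFrame, spacing) -> np.ndarray:
    c = frame[["x", "y", "z"]].to_numpy(dtype=float)
    return c * np.asarray(spacing, dtype=float)


def link_nearest_neighbor(
    frame_t: pd.DataFrame,
    frame_t1: pd.DataFrame,
    config: TrackingConfig | None = None,
) -> list[tuple[int, int]]:
    """One edge per object in frame t to its Euclidean-nearest successor.

    Returns (id_t, id_t1) pairs; distance ties break toward the lowest
    candidate id so runs are deterministic.  Empty frames yield no edges.
    """
    config = config or TrackingConfig()
    if len(frame_t) == 0 or len(frame_t1) == 0:
        return []
    nxt = frame_t1.sort_values("id").reset_index(drop=True)
    d = cdist(_coords(frame_t, config.spacing), _coords(nxt, config.spacing))
    best = np.argmin(d, axis=1)  # argmin takes the first (lowest id) on ties
    edges = []
    for row, j in enumerate(best):
        dist = d[row, j]
        if config.max_link_distance is not None and dist > config.max_link_distance:
            continue
        edges.append((int(frame_t.iloc[row]["id"]), int(nxt.iloc[j]["id"])))
    return edges


def build_tracking_nodes(
    segments: pd.DataFrame,
    seeds: pd.DataFrame,
    labels: np.ndarray,
    config: TrackingConfig | None = None,
    fsmd_col: str = "fsmd_correct",
) -> pd.DataFrame:
    """Node set for one frame: reliable segments plus fallback seeds.

    Segments with FSMD >= beta contribute their centroid; seeds whose
    voxel lies inside a low-FSMD segment's mask replace that segment.
    Seeds falling on background are kept as orphan nodes (better a
    spurious node than a silently lost object).  Node ids are fresh and
    provenance is recorded in ``source`` (segment | seed) and
    ``source_id``.
    """
    config = config or TrackingConfig()
    beta = config.thresholds.beta
    if len(segments) and fsmd_col not in segments.columns:
        raise KeyError(f"segments lack FSMD column {fsmd_col!r}")
    labels = np.asarray(labels)
    low_ids = set()
    rows = []
    for _, rec in segments.iterrows():
        if rec[fsmd_col] >= beta:
            rows.append(
                {"x": rec["x"], "y": rec["y"], "z": rec["z"], "source": "segment",
                 "source_id": int(rec["id"]), "fsmd": float(rec[fsmd_col])}
            )
        else:
            low_ids.add(int(rec["id"]))
    for _, seed in seeds.iterrows():
        z, y, x = int(round(seed["z"])), int(round(seed["y"])), int(round(seed["x"]))
        z = np.clip(z, 0, labels.shape[0] - 1)
        y = np.clip(y, 0, labels.shape[1] - 1)
        x = np.clip(x, 0, labels.shape[2] - 1)
        lab = int(labels[z, y, x])
        if lab in low_ids or lab == 0:
            rows.append(
                {"x": seed["x"], "y": seed["y"], "z": seed["z"], "source": "seed",
                 "source_id": int(seed["id"]),
                 "fsmd": float(seed.get("fsmd_correct", 1.0))}
            )
    nodes = pd.DataFrame(rows, columns=["x", "y", "z", "source", "source_id", "fsmd"])
    nodes.insert(0, "id", np.arange(1, len(nodes) + 1))
    return nodes


def link_frames(
    frames: list[pd.DataFrame], config: TrackingConfig | None = None
) -> LineageGraph:
    """Nearest-neighbour link a sequence of per-frame node tables."""
    config = config or TrackingConfig()
    g = nx.DiGraph()
    for t, frame in enumerate(frames):
        for _, rec in frame.iterrows():
            g.add_node(
                (t, int(rec["id"])),
                x=float(rec["x"]), y=float(rec["y"]), z=float(rec["z"]),
                source=str(rec.get("source", "segment")),
                fsmd=float(rec.get("fsmd", rec.get("fsmd_correct", 1.0))),
            )
    for t in range(len(frames) - 1):
        for a, b in link_nearest_neighbor(frames[t], frames[t + 1], config):
            g.add_edge((t, a), (t + 1, b))
    return assemble_tracks(LineageGraph(g))


def link_with_seed_fallback(
    segment_frames: list[pd.DataFrame],
    seed_frames: list[pd.DataFrame],
    label_frames: list[np.ndarray],
    config: TrackingConfig | None = None,
) -> LineageGraph:
    """Track with the seed fallback for unreliable segments.

    With beta = 0 no segment is unreliable and the result reduces to
    plain nearest-neighbour tracking of the segment centroids.
    """
    config = config or TrackingConfig()
    nodes = [
        build_tracking_nodes(seg, seeds, labels, config)
        for seg, seeds, labels in zip(segment_frames, seed_frames, label_frames)
    ]
    return link_frames(nodes, config)


def assemble_tracks(lineage: LineageGraph) -> LineageGraph:
    """Assign stable track ids along linkage chains.

    A track follows a node's out-edge as long as the successor has
    exactly one incoming edge; a node receiving two or more incoming
    edges starts a new (merged) track segment.  Division-style fan-out
    (out-degree >= 2 cannot occur under plain NN linking but is handled:
    each extra child starts a new track).
    """
    g = lineage.graph
    track_id = 0
    for node in sorted(g.nodes):
        if "track" in g.nodes[node]:
            continue
        track_id += 1
        cur = node
        g.nodes[cur]["track"] = track_id
        while True:
            succs = list(g.successors(cur))
            if len(succs) != 1:
                break
            nxt = succs[0]
            if g.in_degree(nxt) != 1 or "track" in g.nodes[nxt]:
                break
            g.nodes[nxt]["track"] = track_id
            cur = nxt
    return lineage
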