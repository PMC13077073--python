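"""Locomotion-state-resolved functional connectivity graphs.

Neurons are nodes; an edge joins every unordered pair whose Pearson
correlation exceeds a threshold (strictly greater, signed r). Connectivity
comparisons use threshold 0.3; node-level graph metrics (degree, clustering
coefficient, strength) use threshold 0.1, following the convention of
state-comparison studies in mesoscale calcium imaging.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .calcium import correlation_matrix
from .core import DffTraces, LocomotionTrace

__all__ = [
    "StateMask",
    "classify_locomotion",
    "ConnectivityGraph",
    "build_connectivity_graph",
    "compare_states",
    "graph_metrics",
]


@dataclass
class StateMask:
    """Per-frame stationary/moving labels with occupancy and speed stats."""

    moving: np.ndarray  # boolean, True = moving
    fractions: dict[str, float] = field(default_factory=dict)
    speed_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    empty_states: list[str] = field(default_factory=list)

    @property
    def stationary(self) -> np.ndarray:
        return ~self.moving


def classify_locomotion(
    trace: LocomotionTrace,
    speed_threshold_mm_s: float = 10.0,
    min_bout_s: float = 0.5,
    smooth_s: float = 0.5,
) -> StateMask:
    """Threshold smoothed speed into stationary/moving states.

    The speed trace is boxcar-smoothed over ``smooth_s``; a frame is moving
    iff the smoothed speed >= threshold. Bouts shorter than ``min_bout_s``
    are merged into the surrounding state (shortest first). Per-state
    fractions and mean +- SD speeds are computed on the raw trace.
    """
    speed = trace.speed_mm_s
    n = len(speed)
    width = max(1, int(round(smooth_s * trace.frame_rate_hz)))
    smoothed = ndimage.uniform_filter1d(speed, size=width, mode="nearest")
    moving = smoothed >= speed_threshold_mm_s

    min_frames = int(round(min_bout_s * trace.frame_rate_hz))
    if min_frames > 1:
        moving = _merge_short_bouts(moving, min_frames)

    frac_moving = float(moving.mean())
    fractions = {"stationary": 1.0 - frac_moving, "moving": frac_moving}
    speed_stats: dict[str, tuple[float, float]] = {}
    empty: list[str] = []
    for name, sel in (("stationary", ~moving), ("moving", moving)):
        if sel.any():
            speed_stats[name] = (float(speed[sel].mean()), float(speed[sel].std()))
        else:
            speed_stats[name] = (np.nan, np.nan)
            empty.append(name)
    return StateMask(moving=moving, fractions=fractions, speed_stats=speed_stats,
                     empty_states=empty)


def _merge_short_bouts(moving: np.ndarray, min_frames: int) -> np.ndarray:
    """Flip bouts shorter than min_frames into the surrounding state,
    shortest bouts first, until none remain (interior bouts only)."""
    moving = moving.copy()
    changed = True
    while changed:
        changed = False
        bounds = np.flatnonzero(np.diff(moving.astype(int))) + 1
        edges = np.concatenate([[0], bounds, [len(moving)]])
        lengths = np.diff(edges)
        order = np.argsort(lengths)
        for k in order:
            s, e = edges[k], edges[k + 1]
            if e - s >= min_frames:
                continue
            if s == 0 and e == len(moving):
                break
            moving[s:e] = ~moving[s]
            changed = True
            break
    return moving


@dataclass
class ConnectivityGraph:
    """Thresholded Pearson-correlation graph over neurons."""

    graph: nx.Graph
    threshold: float
    state: Optional[str] = None
    intra_edges: int = 0
    inter_edges: int = 0

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_connectivity_graph(
    corr: np.ndarray,
    region_labels: Sequence[str],
    threshold: float = 0.3,
    hemisphere_labels: Optional[Sequence[str]] = None,
    use_absolute: bool = False,
    state: Optional[str] = None,
) -> ConnectivityGraph:
    """Edges for every unordered pair with r > threshold (strict, signed r by
    default; ``use_absolute`` switches to |r|). Edge counts are split into
    intra-region and inter-region by the label vector."""
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    if len(region_labels) != n:
        raise ValueError(
            f"label vector length {len(region_labels)} does not match {n} neurons"
        )
    if hemisphere_labels is not None and len(hemisphere_labels) != n:
        raise ValueError("hemisphere label vector length mismatch")

    g = nx.Graph()
    for i in range(n):
        g.add_node(
            i,
            region=region_labels[i],
            hemisphere=hemisphere_labels[i] if hemisphere_labels is not None else None,
        )
    intra = inter = 0
    values = np.abs(corr) if use_absolute else corr
    iu, ju = np.triu_indices(n, k=1)
    sel = np.isfinite(values[iu, ju]) & (values[iu, ju] > threshold)
    for i, j in zip(iu[sel], ju[sel]):
        g.add_edge(int(i), int(j), weight=float(corr[i, j]))
        if region_labels[i] == region_labels[j]:
            intra += 1
        else:
            inter += 1
    return ConnectivityGraph(
        graph=g, threshold=threshold, state=state, intra_edges=intra, inter_edges=inter
    )


def compare_states(
    dff: DffTraces,
    state_mask: StateMask,
    region_labels: Sequence[str],
    threshold: float = 0.3,
    min_frames: int = 30,
) -> tuple[dict[str, ConnectivityGraph], pd.DataFrame]:
    """Stationary vs moving connectivity at a common threshold.

    Correlation matrices are computed separately on the stationary and moving
    frames, thresholded identically, and the change in intra-/inter-regional
    edge counts reported. Each state needs >= ``min_frames`` frames.
    """
    for name, sel in (("stationary", state_mask.stationary), ("moving", state_mask.moving)):
        if sel.sum() < min_frames:
            raise ValueError(
                f"state {name!r} has only {int(sel.sum())} frames (< {min_frames}); "
                "record longer or relax the state classification"
            )
    graphs: dict[str, ConnectivityGraph] = {}
    for name, sel in (("stationary", state_mask.stationary), ("moving", state_mask.moving)):
        corr = correlation_matrix(dff, frame_mask=sel, min_frames=min_frames)
        graphs[name] = build_connectivity_graph(
            corr, region_labels, threshold=threshold, state=name
        )
    rows = []
    for scope in ("intra", "inter", "total"):
        stat = getattr(graphs["stationary"], f"{scope}_edges") if scope != "total" else graphs["stationary"].n_edges
        mov = getattr(graphs["moving"], f"{scope}_edges") if scope != "total" else graphs["moving"].n_edges
        rows.append({"scope": scope, "stationary": stat, "moving": mov, "delta": mov - stat})
    regions = sorted(set(region_labels))
    for reg in regions:
        per = {}
        for name, cg in graphs.items():
            cnt = sum(
                1
                for u, v in cg.graph.edges
                if cg.graph.nodes[u]["region"] == reg and cg.graph.nodes[v]["region"] == reg
            )
            per[name] = cnt
        rows.append(
            {"scope": f"intra:{reg}", "stationary": per["stationary"],
             "moving": per["moving"], "delta": per["moving"] - per["stationary"]}
        )
    return graphs, pd.DataFrame(rows)


def graph_metrics(
    corr: np.ndarray,
    region_labels: Sequence[str] | None = None,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-node degree, clustering coefficient and strength.

    Degree and clustering coefficient are computed on the graph binarized at
    r > threshold (clustering = unweighted triangle ratio); strength is the
    sum of suprathreshold edge weights at the node. Isolated nodes get 0 for
    all three.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    labels = list(region_labels) if region_labels is not None else ["all"] * n
    cg = build_connectivity_graph(corr, labels, threshold=threshold)
    g = cg.graph
    clustering = nx.clustering(g)
    rows = []
    for i in range(n):
        nbrs = list(g.neighbors(i))
        strength = float(sum(g[i][j]["weight"] for j in nbrs))
        rows.append(
            {
                "node": i,
                "region": labels[i],
                "degree": len(nbrs),
                "clustering": float(clustering[i]),
                "strength": strength,
            }
        )
    return pd.DataFrame(rows)
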