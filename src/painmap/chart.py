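"""Topological feature chart (Mapper).

Features become points in trial space: the z-scored feature matrix is
transposed so each of the 155 features is a point whose coordinates are its
values over all trials.  The Mapper pipeline then runs: (1) Euclidean
distances between feature points; (2) a one-dimensional lens — the distance
to the k-th nearest neighbour (k = 2), an inverse density measure; (3) an
overlapping interval cover of the lens range (N regions overlapping by L of
their length); (4) Ward hierarchical clustering of each region's members;
(5) a graph with one node per cluster and an edge wherever two nodes share
features, weighted by the shared count.

Nodes are annotated with size, mean lens value, and modality composition;
named feature sets can be tagged onto the nodes they touch.  Export targets
are GraphML (via networkx) plus a JSON companion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, ward
from scipy.spatial.distance import pdist, squareform

from .featurebank import FeatureMatrix, PREFIX_MODALITY


@dataclass
class FeaturePointCloud:
    names: list[str]
    points: np.ndarray      # (n_features, n_trials)
    distances: np.ndarray   # (n_features, n_features), Euclidean


@dataclass
class CoverInterval:
    low: float
    high: float
    members: np.ndarray     # feature indices with lens in [low, high]


@dataclass
class ChartNode:
    node_id: int
    features: list[str]
    mean_lens: float
    modality_proportions: dict[str, float]
    region: int
    tags: list[str] = field(default_factory=list)


@dataclass
class FeatureChart:
    nodes: list[ChartNode]
    edges: list[tuple[int, int, int]]   # (node a, node b, shared-feature count)
    lens: dict[str, float]
    params: dict

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            attrs = {
                "size": len(node.features),
                "mean_lens": node.mean_lens,
                "features": ",".join(node.features),
                "region": node.region,
                "tags": ",".join(node.tags),
            }
            for prefix, frac in node.modality_proportions.items():
                attrs[f"prop_{prefix}"] = frac
            g.add_node(node.node_id, **attrs)
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())


def feature_point_cloud(matrix: FeatureMatrix) -> FeaturePointCloud:
    """Transpose the z-scored matrix so features are points; Euclidean distances."""
    if matrix.normalization != "zscored":
        raise ValueError("point cloud requires a z-scored feature matrix")
    pts = matrix.values.to_numpy().T.copy()
    dist = squareform(pdist(pts, metric="euclidean"))
    return FeaturePointCloud(list(matrix.values.columns), pts, dist)


def knn_filter(cloud: FeaturePointCloud, k: int = 2) -> np.ndarray:
    """Lens value per feature: distance to its k-th nearest other point."""
    n = len(cloud.names)
    if not (1 <= k < n):
        raise ValueError(f"k must be in [1, {n - 1}]")
    d = cloud.distances.copy()
    np.fill_diagonal(d, np.inf)
    return np.sort(d, axis=1)[:, k - 1]


def build_cover(lens: np.ndarray, n_intervals: int = 4, overlap: float = 0.5) -> list[CoverInterval]:
    """Uniform overlapping cover of [min lens, max lens].

    Interval length ℓ = range / (N − (N−1)·L) and step ℓ·(1−L), so consecutive
    intervals overlap by the fraction L of their length; membership is
    boundary-inclusive.  A constant lens degenerates to a single interval.
    """
    if n_intervals < 1 or not (0 <= overlap < 1):
        raise ValueError("need n_intervals >= 1 and 0 <= overlap < 1")
    lens = np.asarray(lens, dtype=float)
    lo, hi = float(lens.min()), float(lens.max())
    if hi == lo or n_intervals == 1:
        return [CoverInterval(lo, hi, np.arange(len(lens)))]
    length = (hi - lo) / (n_intervals - (n_intervals - 1) * overlap)
    step = length * (1 - overlap)
    cover = []
    for i in range(n_intervals):
        a = lo + i * step
        b = a + length
        if i == n_intervals - 1:
            b = hi  # guard the top boundary against float round-off
        members = np.nonzero((lens >= a - 1e-12) & (lens <= b + 1e-12))[0]
        cover.append(CoverInterval(a, b, members))
    return cover


def cluster_region(member_idx: np.ndarray, cloud: FeaturePointCloud) -> list[np.ndarray]:
    """Ward clustering of one cover region's features.

    The cluster count comes from the largest-gap heuristic on the linkage
    merge heights: cut at the first gap exceeding mean + 1 SD of the gaps;
    if no gap stands out the region stays one cluster.  The gap statistic is
    mathematically mute for regions of four or fewer points (with two or
    fewer gaps a single dominant gap can never exceed mean + SD), so those
    small regions are instead cut at a global scale reference — the mean
    off-diagonal distance of the whole cloud — which separates members whose
    mutual distance is large on the scale of the dataset while leaving tight
    pairs whole.
    """
    member_idx = np.asarray(member_idx)
    if len(member_idx) == 0:
        raise ValueError("empty cover region")
    if len(member_idx) == 1:
        return [member_idx]
    pts = cloud.points[member_idx]
    Z = ward(pts)
    heights = Z[:, 2]
    cut = None
    if len(heights) >= 4:  # at least 3 gaps: the statistic can fire
        gaps = np.diff(heights)
        thresh = gaps.mean() + gaps.std(ddof=0)
        big = np.nonzero(gaps > thresh + 1e-15)[0]
        if len(big):
            cut = 0.5 * (heights[big[0]] + heights[big[0] + 1])
    else:
        n = cloud.distances.shape[0]
        global_scale = float(cloud.distances.sum() / (n * (n - 1)))
        if heights.max() > global_scale:
            cut = global_scale
    if cut is None:
        labels = np.ones(len(member_idx), dtype=int)
    else:
        labels = fcluster(Z, t=cut, criterion="distance")
    return [member_idx[labels == lab] for lab in np.unique(labels)]


def assemble_chart(
    region_clusters: list[list[np.ndarray]],
    cloud: FeaturePointCloud,
    lens: np.ndarray,
    params: dict | None = None,
) -> FeatureChart:
    """One node per cluster; edges where node feature sets intersect."""
    nodes: list[ChartNode] = []
    sets: list[set[int]] = []
    nid = 0
    for region, clusters in enumerate(region_clusters):
        for idx in clusters:
            feats = [cloud.names[i] for i in idx]
            prefixes = [f[0] for f in feats]
            props = {
                p: prefixes.count(p) / len(prefixes)
                for p in sorted(set(PREFIX_MODALITY))
            }
            nodes.append(
                ChartNode(
                    node_id=nid,
                    features=feats,
                    mean_lens=float(np.mean(lens[idx])),
                    modality_proportions=props,
                    region=region,
                )
            )
            sets.append(set(int(i) for i in idx))
            nid += 1
    edges = []
    for a in range(len(sets)):
        for b in range(a + 1, len(sets)):
            shared = len(sets[a] & sets[b])
            if shared:
                edges.append((a, b, shared))
    return FeatureChart(
        nodes=nodes,
        edges=edges,
        lens={cloud.names[i]: float(lens[i]) for i in range(len(cloud.names))},
        params=params or {},
    )


def build_feature_chart(
    matrix: FeatureMatrix, k: int = 2, n_intervals: int = 4, overlap: float = 0.5
) -> FeatureChart:
    """Full Mapper pipeline from a z-scored feature matrix."""
    cloud = feature_point_cloud(matrix)
    lens = knn_filter(cloud, k)
    cover = build_cover(lens, n_intervals, overlap)
    clusters = [cluster_region(iv.members, cloud) for iv in cover if len(iv.members)]
    chart = assemble_chart(clusters, cloud, lens, {"k": k, "N": n_intervals, "L": overlap})
    return chart


def annotate_feature_sets(chart: FeatureChart, named_sets: dict[str, list[str]]) -> FeatureChart:
    """Tag each node with the named feature sets its members belong to."""
    known = set(chart.lens)
    for set_name, feats in named_sets.items():
        unknown = [f for f in feats if f not in known]
        if unknown:
            raise ValueError(f"unknown feature names in set {set_name}: {unknown}")
    for node in chart.nodes:
        members = set(node.features)
        for set_name, feats in named_sets.items():
            if members & set(feats) and set_name not in node.tags:
                node.tags.append(set_name)
    return chart


def export_chart(chart: FeatureChart, graphml_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write GraphML (node size / mean lens / modality proportions / tags,
    edge weights) and an optional JSON companion."""
    nx.write_graphml(chart.to_networkx(), str(graphml_path))
    if json_path is not None:
        payload = {
            "params": chart.params,
            "lens": chart.lens,
            "nodes": [
                {
                    "id": n.node_id,
                    "features": n.features,
                    "mean_lens": n.mean_lens,
                    "modality_proportions": n.modality_proportions,
                    "region": n.region,
                    "tags": n.tags,
                }
                for n in chart.nodes
            ],
            "edges": [{"a": a, "b": b, "shared": w} for a, b, w in chart.edges],
        }
        Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True))
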