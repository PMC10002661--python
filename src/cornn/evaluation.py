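"""Tractogram comparison battery: bundles, overlap, connectomes, graphs.

Bundle geometry: streamline count, mean length (sum of segment lengths),
mean span (endpoint-to-endpoint distance), voxel-mask volume and exposed
surface area.  Overlap: Dice on binarized traversal masks and the bundle
adjacency distance (symmetrized mean nearest-neighbour MDF between equally
resampled streamlines; MDF = min of direct and flipped mean point-wise
distance).

Connectomes: endpoint parcel pairs accumulate a streamline-count matrix and
a mean-length matrix (symmetric, zero diagonal; streamlines with an
unlabeled endpoint are dropped).  Graph summaries on the count-weighted
connectome: maximum modularity over seeded greedy/Louvain restarts, average
betweenness centrality and characteristic path length with edge distance
1 / weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .grids import ImageGrid, world_to_voxel

__all__ = [
    "BundleMeasures",
    "Connectome",
    "bundle_measures",
    "traversal_mask",
    "voxel_dice",
    "resample_streamline",
    "mdf",
    "bundle_adjacency",
    "build_connectome",
    "connectome_correlation",
    "graph_measures",
    "percent_difference",
]


@dataclass
class BundleMeasures:
    streamline_count: int
    mean_length: float  # mm
    mean_span: float  # mm
    volume: float  # mm^3
    surface_area: float  # mm^2

    def as_dict(self):
        return {
            "streamline_count": self.streamline_count,
            "mean_length": self.mean_length,
            "mean_span": self.mean_span,
            "volume": self.volume,
            "surface_area": self.surface_area,
        }


@dataclass
class Connectome:
    labels: np.ndarray  # parcel ids (nodes)
    count_matrix: np.ndarray  # symmetric ints, zero diagonal
    length_matrix: np.ndarray  # symmetric mean lengths (mm)


def _points_of(s):
    return s.points if hasattr(s, "points") else np.asarray(s, float)


def traversal_mask(bundle, grid: ImageGrid) -> np.ndarray:
    """Boolean voxel mask of all voxels traversed by any streamline.

    Traversal is detected by densely resampling each segment at quarter-voxel
    steps and rounding to the nearest voxel.
    """
    dims = np.asarray(grid.shape)
    mask = np.zeros(grid.shape, dtype=bool)
    step = 0.25 * float(np.min(grid.voxel_size))
    for s in bundle:
        pts = _points_of(s)
        seg = np.diff(pts, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        dense = [pts[:1]]
        for i in range(len(seg)):
            k = max(int(np.ceil(seglen[i] / step)), 1)
            f = (np.arange(1, k + 1) / k)[:, None]
            dense.append(pts[i] + f * seg[i])
        dense = np.concatenate(dense, axis=0)
        v = np.rint(world_to_voxel(grid, dense)).astype(np.int64)
        keep = np.all((v >= 0) & (v < dims), axis=1)
        v = v[keep]
        mask[v[:, 0], v[:, 1], v[:, 2]] = True
    return mask


def bundle_measures(bundle, grid: ImageGrid) -> BundleMeasures:
    """Count, mean length/span, and voxel-mask volume/surface of a bundle."""
    if len(bundle) == 0:
        return BundleMeasures(0, np.nan, np.nan, np.nan, np.nan)
    lengths = []
    spans = []
    for s in bundle:
        pts = _points_of(s)
        lengths.append(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        spans.append(np.linalg.norm(pts[-1] - pts[0]))
    mask = traversal_mask(bundle, grid)
    vs = grid.voxel_size
    vox_vol = float(np.prod(vs))
    n_vox = int(mask.sum())
    # exposed faces: per axis, count faces between in-mask and out-of-mask
    area = 0.0
    for ax in range(3):
        face = float(np.prod(np.delete(vs, ax)))
        padded = np.pad(mask, 1)
        diff = padded.astype(np.int8) - np.roll(padded, 1, axis=ax)
        area += np.abs(diff).sum() * face
    return BundleMeasures(
        streamline_count=len(bundle),
        mean_length=float(np.mean(lengths)),
        mean_span=float(np.mean(spans)),
        volume=n_vox * vox_vol,
        surface_area=float(area),
    )


def voxel_dice(bundle_a, bundle_b, grid: ImageGrid) -> float:
    """2 |A ∩ B| / (|A| + |B|) on traversal masks; NaN if both empty."""
    a = traversal_mask(bundle_a, grid)
    b = traversal_mask(bundle_b, grid)
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def resample_streamline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to n points equidistant along its arc length."""
    pts = np.asarray(points, float)
    if len(pts) == 1:
        return np.repeat(pts, n, axis=0)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, arc, pts[:, k])
    return out


def mdf(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum direct-flip mean point-wise distance (equal point counts)."""
    direct = np.linalg.norm(a - b, axis=1).mean()
    flipped = np.linalg.norm(a - b[::-1], axis=1).mean()
    return float(min(direct, flipped))


def bundle_adjacency(bundle_a, bundle_b, n_resample: int = 20) -> float:
    """Symmetrized mean nearest-streamline MDF distance between bundles (mm)."""
    ra = np.stack([resample_streamline(_points_of(s), n_resample) for s in bundle_a])
    rb = np.stack([resample_streamline(_points_of(s), n_resample) for s in bundle_b])
    # pairwise MDF matrix, vectorized over point pairs
    diff = ra[:, None, :, :] - rb[None, :, :, :]
    direct = np.linalg.norm(diff, axis=3).mean(axis=2)
    diff_f = ra[:, None, :, :] - rb[None, :, ::-1, :]
    flipped = np.linalg.norm(diff_f, axis=3).mean(axis=2)
    d = np.minimum(direct, flipped)  # (|A|, |B|)
    return float(0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean()))


def build_connectome(tractogram, parcellation: np.ndarray, grid: ImageGrid) -> Connectome:
    """Count and mean-length matrices over endpoint parcel pairs.

    Endpoint parcels come from nearest-voxel lookup in the integer
    ``parcellation`` (0 = unlabeled).  Streamlines with an unlabeled
    endpoint or both endpoints in the same parcel contribute no edge.
    """
    labels = np.unique(parcellation)
    labels = labels[labels > 0]
    index = {p: i for i, p in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    lengths = np.zeros((k, k))
    dims = np.asarray(grid.shape)
    for s in tractogram:
        pts = _points_of(s)
        ends = np.rint(world_to_voxel(grid, pts[[0, -1]])).astype(np.int64)
        if np.any(ends < 0) or np.any(ends >= dims):
            continue
        pa = parcellation[tuple(ends[0])]
        pb = parcellation[tuple(ends[1])]
        if pa == 0 or pb == 0 or pa == pb:
            continue
        i, j = index[pa], index[pb]
        length = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        counts[i, j] += 1
        counts[j, i] += 1
        lengths[i, j] += length
        lengths[j, i] += length
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_len = np.where(counts > 0, lengths / np.maximum(counts, 1), 0.0)
    return Connectome(labels=labels, count_matrix=counts, length_matrix=mean_len)


def connectome_correlation(a: Connectome, b: Connectome, weight: str = "count") -> float:
    """Pearson r over strictly-upper-triangle edges (zeros included)."""
    if not np.array_equal(a.labels, b.labels):
        raise ValueError("connectomes have different node sets")
    ma = a.count_matrix if weight == "count" else a.length_matrix
    mb = b.count_matrix if weight == "count" else b.length_matrix
    iu = np.triu_indices(len(a.labels), k=1)
    x, y = ma[iu].astype(float), mb[iu].astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def graph_measures(c: Connectome, seed: int = 0, n_restarts: int = 10) -> dict:
    """Max modularity, average betweenness centrality, characteristic path
    length on the count-weighted graph (edge distance = 1 / weight)."""
    w = c.count_matrix
    n = len(c.labels)
    if n == 0 or w.sum() == 0:
        return {
            "max_modularity": float("nan"),
            "avg_betweenness_centrality": float("nan"),
            "characteristic_path_length": float("nan"),
        }
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, weight=float(w[i, j]), distance=1.0 / float(w[i, j]))
    # maximum modularity over greedy + seeded Louvain restarts
    best_q = -np.inf
    try:
        part = nx.community.greedy_modularity_communities(g, weight="weight")
        best_q = nx.community.modularity(g, part, weight="weight")
    except (ZeroDivisionError, nx.NetworkXError):
        pass
    for r in range(n_restarts):
        part = nx.community.louvain_communities(g, weight="weight", seed=seed + r)
        q = nx.community.modularity(g, part, weight="weight")
        best_q = max(best_q, q)
    bc = nx.betweenness_centrality(g, weight="distance", normalized=True)
    avg_bc = float(np.mean(list(bc.values())))
    # characteristic path length: mean shortest path over connected ordered pairs
    tot, cnt = 0.0, 0
    for src, dists in nx.all_pairs_dijkstra_path_length(g, weight="distance"):
        for dst, d in dists.items():
            if dst != src:
                tot += d
                cnt += 1
    cpl = tot / cnt if cnt else float("nan")
    return {
        "max_modularity": float(best_q),
        "avg_betweenness_centrality": avg_bc,
        "characteristic_path_length": float(cpl),
    }


def percent_difference(x: float, reference: float) -> float:
    """100 |x - reference| / reference; NaN guard on zero reference."""
    if reference == 0:
        return float("nan")
    return float(100.0 * abs(x - reference) / abs(reference))
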