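"""Vessel segmentation, centerline extraction and capillary geometry.

The pipeline mirrors the standard two-photon angiogram workflow: binarize
the stack into vasculature vs. background, thin the mask to a one-voxel
skeleton, organize the skeleton into a junction/endpoint graph whose edges
are junction-to-junction capillary segments, then measure each segment's
diameter (mean of twice the distance-to-background along the centerline),
path length, and tortuosity (path length over the Euclidean chord).
Analyses downstream are restricted to capillaries by excluding segments
with diameter greater than 10 μm.

The segmenter here is a classical intensity-threshold stand-in with the
same output contract as a learned segmenter (a boolean mask congruent with
the stack), so either can feed the rest of the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize, remove_small_objects

from .synthetic import AngiogramStack

__all__ = [
    "VesselMask",
    "CenterlineGraph",
    "CapillarySegment",
    "segment_vessels",
    "extract_centerlines",
    "identify_segments",
    "filter_capillaries",
    "capillary_density",
    "CAPILLARY_MAX_DIAMETER_UM",
]

logger = logging.getLogger(__name__)

# Segments with diameter above this are arterioles/venules, not capillaries.
CAPILLARY_MAX_DIAMETER_UM = 10.0

# Edges shorter than this many skeleton voxels are thinning artifacts.
MIN_SEGMENT_VOXELS = 3


@dataclass
class VesselMask:
    """Boolean vasculature mask congruent with its source stack."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-dimensional")


@dataclass
class CenterlineGraph:
    """Skeleton organized as nodes (junctions/endpoints) and voxel-path edges.

    nodes: node id -> representative (z, y, x) voxel; edges: list of
    (node_a, node_b, path) where path is the ordered (N, 3) voxel array
    from a to b (inclusive).
    """

    nodes: dict[int, tuple[int, int, int]]
    edges: list[tuple[int, int, np.ndarray]]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class CapillarySegment:
    """A junction-to-junction vessel segment with its geometric metrics."""

    segment_id: int
    centerline_um: np.ndarray  # (N, 3) μm, (z, y, x)
    path_voxels: np.ndarray  # (N, 3) int voxel indices
    diameter_um: float
    length_um: float
    euclidean_chord_um: float
    tortuosity: float

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.tortuosity < 1.0 - 1e-9:
            raise ValueError("tortuosity must be >= 1")


def segment_vessels(stack: AngiogramStack, smooth_sigma: float = 0.5,
                    invert: bool = False, min_voxels: int = 64,
                    closing_radius: int = 1) -> VesselMask:
    """Binarize a stack into vasculature vs. background.

    Otsu threshold on a lightly smoothed stack, followed by morphological
    closing and removal of small speckle components.  ``invert=True``
    handles inverted-contrast data (dark vessels on bright background).
    A stack with no discernible signal yields an empty mask and a warning.
    """
    if stack.n_frames < 1:
        raise ValueError("stack must contain at least one frame")
    data = stack.data.astype(float)
    if invert:
        data = data.max() - data
    smoothed = ndimage.gaussian_filter(data, smooth_sigma) if smooth_sigma > 0 else data
    lo, hi = smoothed.min(), smoothed.max()
    if hi - lo < 1e-9 * max(abs(hi), 1.0):
        warnings.warn("stack has no contrast; returning an empty mask")
        return VesselMask(np.zeros(stack.data.shape, bool), stack.voxel_size)
    # half-maximum threshold between the background level (median: vessels
    # fill a few percent of the volume) and the lumen brightness; unlike
    # Otsu this keeps the boundary of a blurred tube at its true radius
    bg_level = float(np.median(smoothed))
    fg_level = float(np.percentile(smoothed, 99.5))
    thr = 0.5 * (bg_level + fg_level)
    mask = smoothed > thr
    # guard against thresholding pure background noise: foreground should be
    # clearly brighter than background
    fg, bg = smoothed[mask], smoothed[~mask]
    if fg.size == 0 or bg.size == 0 or fg.mean() < bg.mean() + 3.0 * bg.std():
        warnings.warn("no vessel-like signal found; returning an empty mask")
        return VesselMask(np.zeros(stack.data.shape, bool), stack.voxel_size)
    if closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=_ball(closing_radius))
    # cell shadows are nearly as dark as background and cut each lumen into
    # fragments; reconnect fragment pairs whose straight connection runs
    # through shadow-level (above-background) intensity
    liberal_thr = bg_level + max(
        3.0 * _background_sigma(smoothed), 0.08 * (fg_level - bg_level)
    )
    mask = _bridge_shadow_gaps(mask, smoothed, liberal_thr)
    mask = remove_small_objects(mask, max_size=min_voxels - 1)
    return VesselMask(mask, stack.voxel_size)


def _ball(radius: int) -> np.ndarray:
    g = np.indices((2 * radius + 1,) * 3) - radius
    return (g ** 2).sum(axis=0) <= radius ** 2


def _background_sigma(smoothed: np.ndarray) -> float:
    med = np.median(smoothed)
    return 1.4826 * float(np.median(np.abs(smoothed - med)))


def _bridge_shadow_gaps(mask: np.ndarray, smoothed: np.ndarray,
                        liberal_thr: float, max_gap: float = 14.0) -> np.ndarray:
    """Reconnect mask fragments separated by dark cell shadows.

    For every pair of nearby connected components, the straight path
    between their closest voxels is accepted as a lumen gap only if the
    intensity along it stays above the shadow (liberal) threshold —
    background never does — and is painted as a cylinder matching the
    local tube radius.  Operates in voxel units (gap limit ``max_gap``
    voxels).
    """
    from scipy.spatial import cKDTree

    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n <= 1:
        return mask
    comps = [np.argwhere(labels == i + 1) for i in range(n)]
    trees = [cKDTree(c) for c in comps]
    edt = ndimage.distance_transform_edt(mask)
    out = mask.copy()
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    centers = [c.mean(axis=0) for c in comps]
    radii_bb = [np.linalg.norm(c - centers[k], axis=1).max() for k, c in enumerate(comps)]
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centers[i] - centers[j]) > radii_bb[i] + radii_bb[j] + max_gap:
                continue
            d, idx = trees[j].query(comps[i])
            k = int(np.argmin(d))
            if d[k] > max_gap:
                continue
            p, q = comps[i][k].astype(float), comps[j][idx[k]].astype(float)
            n_samp = max(3, int(np.ceil(d[k] * 2)))
            line = p + (q - p) * np.linspace(0.0, 1.0, n_samp)[:, None]
            vals = ndimage.map_coordinates(smoothed, line.T, order=1)
            if vals.min() < liberal_thr:
                continue  # the path dips to background level: a real gap
            if find(i) == find(j):
                continue
            parent[find(i)] = find(j)
            # local tube radius from the distance transform near both ends
            r = max(
                1.0,
                float(edt[tuple(comps[i][k])]),
                float(edt[tuple(comps[j][idx[k]])]),
                _local_radius(edt, comps[i][k]),
                _local_radius(edt, comps[j][idx[k]]),
            )
            _paint_cylinder(out, p, q, r)
    return out


def _local_radius(edt: np.ndarray, voxel: np.ndarray, reach: int = 4) -> float:
    lo = np.maximum(voxel - reach, 0)
    hi = np.minimum(voxel + reach + 1, edt.shape)
    region = edt[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return float(region.max()) if region.size else 1.0


def _paint_cylinder(mask: np.ndarray, p: np.ndarray, q: np.ndarray,
                    radius: float) -> None:
    lo = np.maximum(np.floor(np.minimum(p, q) - radius).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p, q) + radius).astype(int) + 1, mask.shape)
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    axis = q - p
    alen = np.linalg.norm(axis)
    if alen < 1e-9:
        return
    u = axis / alen
    t = np.clip((pts - p) @ u, 0.0, alen)
    dist = np.linalg.norm(pts - (p + t[:, None] * u), axis=1)
    inside = pts[dist <= radius].astype(int)
    mask[inside[:, 0], inside[:, 1], inside[:, 2]] = True


def _neighbor_offsets() -> np.ndarray:
    offs = [(dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)]
    return np.array(offs)


def extract_centerlines(mask: VesselMask) -> CenterlineGraph:
    """Thin the mask to a one-voxel skeleton and organize it into a graph.

    Skeleton voxels with exactly two 26-neighbors are path interior; voxels
    with one neighbor are endpoints and voxels with three or more are
    junctions.  Adjacent junction voxels are merged into a single node.
    Every edge is an ordered 26-connected voxel path between two nodes.
    """
    if not mask.data.any():
        return CenterlineGraph(nodes={}, edges=[])
    skel = skeletonize(mask.data)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return CenterlineGraph(nodes={}, edges=[])
    index = {tuple(c): i for i, c in enumerate(coords)}
    offsets = _neighbor_offsets()
    neighbors: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in offsets:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                neighbors[i].append(j)
    degree = np.array([len(n) for n in neighbors])
    is_node_voxel = degree != 2  # endpoints, junctions, isolated voxels

    # merge adjacent node voxels (junction clusters) into single nodes
    node_of_voxel = -np.ones(len(coords), int)
    node_repr: dict[int, tuple[int, int, int]] = {}
    next_node = 0
    for i in np.flatnonzero(is_node_voxel):
        if node_of_voxel[i] >= 0:
            continue
        group = [i]
        node_of_voxel[i] = next_node
        queue = [i]
        while queue:
            cur = queue.pop()
            for j in neighbors[cur]:
                if is_node_voxel[j] and node_of_voxel[j] < 0:
                    node_of_voxel[j] = next_node
                    group.append(j)
                    queue.append(j)
        # representative: voxel closest to the cluster centroid
        pts = coords[group]
        center = pts.mean(axis=0)
        rep = pts[np.argmin(((pts - center) ** 2).sum(axis=1))]
        node_repr[next_node] = tuple(int(v) for v in rep)
        next_node += 1

    # trace edges: from every node voxel, walk through degree-2 chains
    visited_pairs = set()
    chain_used = np.zeros(len(coords), bool)
    edges = []
    for start in np.flatnonzero(is_node_voxel):
        for nb in neighbors[start]:
            if is_node_voxel[nb]:
                a, b = node_of_voxel[start], node_of_voxel[nb]
                if a != b:
                    key = (min(a, b), max(a, b), -1)
                    if key not in visited_pairs:
                        visited_pairs.add(key)
                        edges.append((a, b, coords[[start, nb]]))
                continue
            if chain_used[nb]:
                continue
            path = [start, nb]
            prev, cur = start, nb
            while not is_node_voxel[cur]:
                chain_used[cur] = True
                nxt = [j for j in neighbors[cur] if j != prev]
                if not nxt:  # open chain end (isolated loop fragment)
                    break
                prev, cur = cur, nxt[0]
                path.append(cur)
            if not is_node_voxel[path[-1]]:
                continue
            a, b = node_of_voxel[start], node_of_voxel[path[-1]]
            edges.append((a, b, coords[path]))
    # pure cycles with no node voxel (rare) are ignored
    nodes, edges = _prune_and_merge(node_repr, edges)
    return CenterlineGraph(nodes=nodes, edges=edges)


def _prune_and_merge(nodes: dict, edges: list, min_spur: int = 10):
    """Remove short spur edges (thinning artifacts at tube walls) and merge
    edge pairs at the degree-2 nodes pruning leaves behind."""
    edges = list(edges)
    while True:
        deg: dict[int, int] = {}
        for a, b, _ in edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        pruned = []
        dropped = False
        contract = None
        for a, b, path in edges:
            if a == b and len(path) < 3 * min_spur:
                dropped = True  # small self-loop (thinning artifact)
                continue
            leaf_spur = len(path) < min_spur and (
                (deg[a] == 1 and deg[b] >= 3) or (deg[b] == 1 and deg[a] >= 3)
            )
            if leaf_spur:
                dropped = True
                continue
            if (contract is None and a != b and len(path) < min_spur
                    and deg[a] >= 3 and deg[b] >= 3):
                contract = (a, b)  # short junction-junction edge: one cluster
                dropped = True
                continue
            pruned.append((a, b, path))
        edges = pruned
        if contract is not None:
            a0, b0 = contract
            edges = [
                (a0 if a == b0 else a, a0 if b == b0 else b, p)
                for a, b, p in edges
            ]
        # merge the two edges meeting at any degree-2 node
        deg = {}
        incident: dict[int, list[int]] = {}
        for k, (a, b, _) in enumerate(edges):
            for n in (a, b):
                deg[n] = deg.get(n, 0) + 1
                incident.setdefault(n, []).append(k)
        merge_node = next(
            (n for n, d in deg.items()
             if d == 2 and len(set(incident[n])) == 2), None
        )
        if merge_node is None:
            if not dropped:
                break
            continue
        k1, k2 = incident[merge_node]
        a1, b1, p1 = edges[k1]
        a2, b2, p2 = edges[k2]
        if b1 != merge_node:
            a1, b1, p1 = b1, a1, p1[::-1]
        if a2 != merge_node:
            a2, b2, p2 = b2, a2, p2[::-1]
        merged = (a1, b2, np.vstack([p1, p2]))
        edges = [e for k, e in enumerate(edges) if k not in (k1, k2)]
        edges.append(merged)
    used = {a for a, _, _ in edges} | {b for _, b, _ in edges}
    nodes = {n: v for n, v in nodes.items() if n in used}
    return nodes, edges


def _smooth_path(pos_um: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing of a voxel path (endpoints pinned).

    A one-voxel skeleton staircases around the true centerline, inflating
    path length by several percent on curved vessels; a short moving
    average removes the staircase without shortening large-scale curvature.
    """
    if len(pos_um) <= window:
        return pos_um
    sm = ndimage.uniform_filter1d(pos_um, size=window, axis=0, mode="nearest")
    sm[0], sm[-1] = pos_um[0], pos_um[-1]
    return sm


def identify_segments(graph: CenterlineGraph, mask: VesselMask) -> list[CapillarySegment]:
    """Measure each graph edge as a capillary segment.

    diameter = 2 x mean Euclidean distance-to-background along the
    centerline; length = sum of inter-voxel steps in μm; tortuosity =
    length / Euclidean chord.  Edges shorter than a minimum voxel count or
    with a degenerate chord are dropped and logged.
    """
    voxel_size = np.asarray(mask.voxel_size, float)
    edt = ndimage.distance_transform_edt(mask.data, sampling=voxel_size)
    segments = []
    sid = 0
    for a, b, path in graph.edges:
        if len(path) < MIN_SEGMENT_VOXELS:
            logger.info("dropping edge %s-%s: only %d voxels", a, b, len(path))
            continue
        pos_um = _smooth_path(path * voxel_size)
        steps = np.linalg.norm(np.diff(pos_um, axis=0), axis=1)
        length = float(steps.sum())
        chord = float(np.linalg.norm(pos_um[-1] - pos_um[0]))
        if chord < 1e-6 or length < 1e-6:
            logger.info("dropping edge %s-%s: degenerate chord/length", a, b)
            continue
        radii = edt[path[:, 0], path[:, 1], path[:, 2]]
        diameter = float(2.0 * radii.mean())
        if diameter <= 0:
            logger.info("dropping edge %s-%s: zero diameter", a, b)
            continue
        segments.append(
            CapillarySegment(
                segment_id=sid,
                centerline_um=pos_um,
                path_voxels=path,
                diameter_um=diameter,
                length_um=length,
                euclidean_chord_um=chord,
                tortuosity=max(1.0, length / chord),
            )
        )
        sid += 1
    return segments


def filter_capillaries(segments: list[CapillarySegment],
                       max_diameter: float = CAPILLARY_MAX_DIAMETER_UM
                       ) -> list[CapillarySegment]:
    """Keep only capillaries: segments with diameter <= ``max_diameter`` μm.

    The boundary value is retained (only strictly larger vessels are
    excluded).  Input order is preserved; the operation is idempotent and
    monotone in the threshold.
    """
    return [s for s in segments if s.diameter_um <= max_diameter]


def capillary_density(segments: list, analyzed_volume_mm3: float) -> float:
    """Segment count per mm³ of analyzed tissue."""
    if analyzed_volume_mm3 <= 0:
        raise ValueError("analyzed volume must be positive")
    return len(segments) / analyzed_volume_mm3


def segments_to_frame(segments: list[CapillarySegment]):
    """Tabulate segments (id, diameter_um, length_um, tortuosity, n_voxels)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [s.segment_id for s in segments],
            "diameter_um": [s.diameter_um for s in segments],
            "length_um": [s.length_um for s in segments],
            "tortuosity": [s.tortuosity for s in segments],
            "n_voxels": [len(s.path_voxels) for s in segments],
        }
    )
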