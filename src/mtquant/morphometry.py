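"""Skeleton-based neurite morphometry: total length and branch points.

Mirrors the common FIJI chain for dendritic-arborization neurons: a
Hessian ridge ("tubeness") enhancement of curvilinear structures, Otsu
thresholding, topology-preserving skeletonization, then measurement on the
skeleton graph.  Length is measured per skeleton branch by resampling the
pixel chain into chords, which removes most of the systematic overestimate
of raw 8-connected step counting on diagonal-ish paths; the classic
1/√2-weighted edge sum remains available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import networkx as nx
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing as binary_closing, disk as disk_footprint, skeletonize

__all__ = [
    "SkeletonGraph",
    "ArborMorphometry",
    "enhance_tubes",
    "skeletonize_mask",
    "total_length",
    "count_branch_points",
    "measure_arbor",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class SkeletonGraph:
    """8-connected pixel graph of a 1-px-wide skeleton.

    Nodes are (row, col) pixel coordinates; edges join 8-neighbors with
    weight 1 (orthogonal) or √2 (diagonal).  Diagonal edges that
    short-circuit an orthogonal pixel pair are suppressed so each step of
    the skeleton is counted once.
    """

    graph: nx.Graph
    pixel_size: float = 1.0  # µm / pixel

    @property
    def n_pixels(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph) \
            if self.graph.number_of_nodes() else 0


@dataclass
class ArborMorphometry:
    total_length: float       # µm
    n_branch_points: int      # after clustering nearby candidates
    n_components: int


def enhance_tubes(image: np.ndarray, scale_sigma: float = 2.0) -> np.ndarray:
    """Hessian ridge measure for bright curvilinear structures.

    For each pixel the Hessian of the Gaussian-smoothed image (scale
    ``scale_sigma``) is diagonalized and the response is max(0, −λ₂) with
    λ₂ the more negative eigenvalue: large on ridges (strong negative
    curvature across the tube axis), ≈0 on flat background.
    """
    image = np.asarray(image, dtype=float)
    # mean-centering cancels the DC residue of the truncated derivative
    # kernels, so a constant image maps to exactly zero
    image = image - image.mean()
    hrr = ndi.gaussian_filter(image, scale_sigma, order=(2, 0))
    hrc = ndi.gaussian_filter(image, scale_sigma, order=(1, 1))
    hcc = ndi.gaussian_filter(image, scale_sigma, order=(0, 2))
    # closed-form smaller eigenvalue of the symmetric 2x2 Hessian
    lam2 = (hrr + hcc) / 2.0 - np.sqrt(((hrr - hcc) / 2.0) ** 2 + hrc ** 2)
    return np.maximum(-lam2, 0.0)


def skeletonize_mask(mask: np.ndarray, pixel_size: float = 1.0) -> SkeletonGraph:
    """Thin a binary mask to 1-px width and build its pixel graph."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return SkeletonGraph(graph=nx.Graph(), pixel_size=pixel_size)
    skel = skeletonize(mask)
    g = nx.Graph()
    coords = np.argwhere(skel)
    pixel_set = {tuple(rc) for rc in coords}
    for r, c in coords:
        g.add_node((int(r), int(c)))
    for r, c in coords:
        # orthogonal edges (scan forward only, each pair once)
        for dr, dc in ((0, 1), (1, 0)):
            nb = (r + dr, c + dc)
            if nb in pixel_set:
                g.add_edge((r, c), nb, weight=1.0)
    for r, c in coords:
        for dr, dc in ((1, 1), (1, -1)):
            nb = (r + dr, c + dc)
            if nb not in pixel_set:
                continue
            # suppress the diagonal when an orthogonal 2-step path exists
            if (r, c + dc) in pixel_set or (r + dr, c) in pixel_set:
                continue
            g.add_edge((r, c), nb, weight=_SQRT2)
    return SkeletonGraph(graph=g, pixel_size=pixel_size)


def _branch_paths(g: nx.Graph) -> list[list[tuple[int, int]]]:
    """Split the skeleton graph into maximal chains between non-degree-2 nodes."""
    paths: list[list[tuple[int, int]]] = []
    anchors = [n for n in g.nodes if g.degree[n] != 2]
    visited_edges: set[frozenset] = set()
    for a in anchors:
        for nb in g.neighbors(a):
            e = frozenset((a, nb))
            if e in visited_edges:
                continue
            path = [a, nb]
            visited_edges.add(e)
            prev, cur = a, nb
            while g.degree[cur] == 2:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                visited_edges.add(frozenset((cur, nxt)))
                path.append(nxt)
                prev, cur = cur, nxt
            paths.append(path)
    # pure cycles (all degree 2) have no anchor; walk them separately
    for comp in nx.connected_components(g):
        if all(g.degree[n] == 2 for n in comp):
            start = next(iter(comp))
            path = [start]
            prev, cur = None, start
            while True:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                path.append(nxt)
                prev, cur = cur, nxt
                if cur == start:
                    break
            paths.append(path)
    return paths


def total_length(
    skeleton: SkeletonGraph,
    method: str = "chord",
    chord_step: int = 5,
) -> float:
    """Total skeleton length in µm.

    ``chord`` (default) resamples every branch's pixel chain at
    ``chord_step``-pixel intervals and sums the Euclidean chord lengths —
    a low-bias digital length estimator (raw 8-connected step counting
    overestimates oblique paths by up to ~8%).  ``edge_sum`` sums the
    1/√2 edge weights directly.
    """
    g = skeleton.graph
    if g.number_of_nodes() == 0:
        return 0.0
    if method == "edge_sum":
        length_px = sum(d["weight"] for _, _, d in g.edges(data=True))
    elif method == "chord":
        length_px = 0.0
        for path in _branch_paths(g):
            pts = np.asarray(path, dtype=float)
            idx = list(range(0, len(pts), chord_step))
            if idx[-1] != len(pts) - 1:
                idx.append(len(pts) - 1)
            sub = pts[idx]
            length_px += float(np.hypot(*np.diff(sub, axis=0).T).sum())
    else:
        raise ValueError(f"unknown length method {method!r}")
    return length_px * skeleton.pixel_size


def count_branch_points(skeleton: SkeletonGraph,
                        cluster_radius: float = 2.0) -> int:
    """Count anatomical branch points on the skeleton.

    Skeleton pixels with ≥3 skeleton neighbors (8-connectivity, before
    diagonal suppression) are branch candidates; candidates within
    ``cluster_radius`` pixels of each other are merged into one branch
    point, since thinning often produces 2–3 adjacent high-degree pixels
    at a single anatomical junction.
    """
    g = skeleton.graph
    if g.number_of_nodes() == 0:
        return 0
    pixel_set = set(g.nodes)
    candidates = []
    for r, c in g.nodes:
        nb = sum((r + dr, c + dc) in pixel_set
                 for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0))
        if nb >= 3:
            candidates.append((r, c))
    if not candidates:
        return 0
    cluster = nx.Graph()
    cluster.add_nodes_from(candidates)
    pts = np.asarray(candidates, dtype=float)
    for i in range(len(pts)):
        d = np.hypot(pts[:, 0] - pts[i, 0], pts[:, 1] - pts[i, 1])
        for j in np.nonzero((d <= cluster_radius) & (np.arange(len(pts)) > i))[0]:
            cluster.add_edge(candidates[i], candidates[int(j)])
    return nx.number_connected_components(cluster)


def measure_arbor(
    image: np.ndarray,
    pixel_size: float,
    *,
    use_tubeness: bool = True,
    tube_sigma: float = 1.5,
    threshold: Optional[float] = None,
    closing_radius: int = 1,
    min_component_px: int = 5,
    cluster_radius: float = 2.0,
    length_method: str = "chord",
) -> ArborMorphometry:
    """Full arbor measurement chain on a single-channel image.

    Ridge enhancement (optional) → Otsu threshold (or ``threshold``) →
    morphological closing to bridge 1–2 px segmentation gaps → removal of
    speck components below ``min_component_px`` → skeletonization → total
    length and clustered branch-point count.
    """
    img = enhance_tubes(image, tube_sigma) if use_tubeness \
        else np.asarray(image, dtype=float)
    thr = float(threshold_otsu(img)) if threshold is None else float(threshold)
    mask = img > thr
    if closing_radius > 0:
        mask = binary_closing(mask, disk_footprint(closing_radius))
    if min_component_px > 0:
        labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
        if n:
            sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= min_component_px) + 1
            mask = np.isin(labels, keep)
    skel = skeletonize_mask(mask, pixel_size=pixel_size)
    return ArborMorphometry(
        total_length=total_length(skel, method=length_method),
        n_branch_points=count_branch_points(skel, cluster_radius=cluster_radius),
        n_components=skel.n_components,
    )
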