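"""Colony merging: fuse oversegmented sparse specimens via a Delaunay graph.

Sparse colonies (Volvox, Microcystis, ...) appear as clouds of visually
disconnected cells, so candidate detection splits them into many blobs. This
stage links every candidate to its spatial neighbours through a Delaunay
triangulation of the candidate centroids, prunes links whose endpoints are
too far apart (centroid distance > 105 μm by default) or too different in
colour (> 15% of the dynamic range per RGB channel by default), and fuses
each surviving connected subgraph into a single candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError

from .candidates import Candidate
from .io import BoundingBox, MicroscopyImage, PipelineConfig, um_to_px
from .segmentation import DYNAMIC_RANGE

Edge = tuple[int, int]


@dataclass
class CandidateGraph:
    """Delaunay adjacency over candidate centroids with pruning state."""

    nodes: list[int]
    edges: set[Edge]
    pruned_edges: set[Edge] = field(default_factory=set)

    @property
    def surviving_edges(self) -> set[Edge]:
        return self.edges - self.pruned_edges


def _as_edge(i: int, j: int) -> Edge:
    return (i, j) if i < j else (j, i)


def build_delaunay_graph(cands: list[Candidate], seed: int = 0) -> CandidateGraph:
    """Delaunay triangulation of the candidate centroids as an edge set.

    0 or 1 candidates give no edges; 2 give the single pair. Degenerate point
    sets (e.g. collinear centroids) fall back to the complete graph so that
    the pruning thresholds still govern merging. Duplicate centroids are
    jittered by 1e-6 px with a seeded generator before triangulation.
    """
    n = len(cands)
    nodes = list(range(n))
    if n <= 1:
        return CandidateGraph(nodes, set())
    pts = np.array([(c.centroid[1], c.centroid[0]) for c in cands], dtype=float)
    if len(np.unique(pts, axis=0)) < n:
        rng = np.random.default_rng(seed)
        pts = pts + rng.uniform(-1e-6, 1e-6, size=pts.shape)
    if n == 2:
        return CandidateGraph(nodes, {(0, 1)})
    try:
        tri = Delaunay(pts)
    except QhullError:
        complete = {(i, j) for i in range(n) for j in range(i + 1, n)}
        return CandidateGraph(nodes, complete)
    edges: set[Edge] = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                edges.add(_as_edge(int(simplex[a]), int(simplex[b])))
    return CandidateGraph(nodes, edges)


def prune_edges(
    graph: CandidateGraph,
    cands: list[Candidate],
    distance_um: float,
    colour_frac: float,
    resolution: float,
    colour_metric: str = "per_channel",
) -> CandidateGraph:
    """Mark edges failing the spatial or colour similarity tests as pruned.

    An edge survives iff the centroid Euclidean distance is ≤
    ``distance_um × resolution`` pixels AND the candidates' mean-RGB
    difference is within ``colour_frac × 255`` — per channel
    (``colour_metric="per_channel"``, any channel exceeding prunes) or as a
    Euclidean RGB distance (``"euclidean"``).
    """
    dist_px = math.inf if math.isinf(distance_um) else um_to_px(distance_um, resolution)
    colour_thresh = colour_frac * DYNAMIC_RANGE
    pruned: set[Edge] = set()
    for i, j in graph.edges:
        ci, cj = cands[i], cands[j]
        d = math.hypot(ci.centroid[0] - cj.centroid[0], ci.centroid[1] - cj.centroid[1])
        if d > dist_px:
            pruned.add((i, j))
            continue
        diff = np.abs(np.asarray(ci.mean_rgb, float) - np.asarray(cj.mean_rgb, float))
        if colour_metric == "per_channel":
            if np.any(diff > colour_thresh):
                pruned.add((i, j))
        elif colour_metric == "euclidean":
            if float(np.linalg.norm(diff)) > colour_thresh:
                pruned.add((i, j))
        else:
            raise ValueError(f"unknown colour_metric {colour_metric!r}")
    return CandidateGraph(list(graph.nodes), set(graph.edges), pruned)


def fuse_components(
    graph: CandidateGraph,
    cands: list[Candidate],
    image: MicroscopyImage | None = None,
) -> list[Candidate]:
    """Fuse each connected component of the surviving graph into one candidate.

    The fused mask is the union of member masks; the bbox is the minimal box
    containing the member bboxes; centroid, area and mean colour are
    recomputed from the union mask (from the image when given, otherwise by
    area-weighted combination of member statistics — exact for disjoint
    members). Singletons pass through unchanged. Output candidates are ordered
    by bbox top-left raster order and re-numbered.
    """
    n = len(cands)
    if n == 0:
        return []
    surviving = graph.surviving_edges
    if surviving:
        rows, cols = zip(*surviving)
        adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    fused: list[Candidate] = []
    for members in groups.values():
        if len(members) == 1:
            fused.append(cands[members[0]])
            continue
        fused.append(_fuse(members, cands, image))
    fused.sort(key=lambda c: (c.bbox.y_min, c.bbox.x_min))
    out = []
    for i, c in enumerate(fused):
        c = Candidate(i, c.contour, c.mask, c.bbox, c.centroid, c.area_px, c.mean_rgb)
        out.append(c)
    return out


def _fuse(members: list[int], cands: list[Candidate],
          image: MicroscopyImage | None) -> Candidate:
    bbox = cands[members[0]].bbox
    for m in members[1:]:
        bbox = bbox.union_with(cands[m].bbox)
    union = np.zeros((bbox.height, bbox.width), dtype=bool)
    for m in members:
        c = cands[m]
        y0 = c.bbox.y_min - bbox.y_min
        x0 = c.bbox.x_min - bbox.x_min
        union[y0:y0 + c.bbox.height, x0:x0 + c.bbox.width] |= c.mask
    rr, cc = np.nonzero(union)
    area = float(union.sum())
    centroid = (float(rr.mean()) + bbox.y_min, float(cc.mean()) + bbox.x_min)
    if image is not None:
        crop = image.pixels[bbox.y_min:bbox.y_max, bbox.x_min:bbox.x_max]
        mean_rgb = crop[union].reshape(-1, 3).mean(axis=0).astype(float)
    else:
        weights = np.array([cands[m].area_px for m in members])
        colours = np.array([cands[m].mean_rgb for m in members], dtype=float)
        mean_rgb = (weights[:, None] * colours).sum(axis=0) / weights.sum()
    contour = np.vstack([np.atleast_2d(cands[m].contour) for m in members])
    return Candidate(0, contour, union, bbox, centroid, area, mean_rgb)


def merge_colonies(
    cands: list[Candidate],
    image: MicroscopyImage,
    config: PipelineConfig,
) -> list[Candidate]:
    """Build → prune → fuse: the full colony-merging stage."""
    if not cands:
        return []
    graph = build_delaunay_graph(cands, seed=config.rng_seed)
    graph = prune_edges(
        graph, cands,
        config.merge_distance_um, config.merge_colour_frac,
        image.resolution, colour_metric=config.colour_metric,
    )
    return fuse_components(graph, cands, image=image)
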