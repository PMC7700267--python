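"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by direct enumeration, flood fill
or closed form, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components of the hole-filled mask, as pixel sets.

    Hole filling: background pixels (4-connected) not reachable from the
    border are holes and become foreground.
    """
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    reachable = np.zeros((h, w), bool)
    q: deque = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not reachable[r, c]:
                reachable[r, c] = True
                q.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not reachable[r, c]:
                reachable[r, c] = True
                q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not reachable[rr, cc]:
                reachable[rr, cc] = True
                q.append((rr, cc))
    filled = mask | ~reachable
    seen = np.zeros((h, w), bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if filled[r, c] and not seen[r, c]:
                comp = set()
                seen[r, c] = True
                q = deque([(r, c)])
                while q:
                    y, x = q.popleft()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and filled[yy, xx] \
                                    and not seen[yy, xx]:
                                seen[yy, xx] = True
                                q.append((yy, xx))
                comps.append(comp)
    return comps


def _circumcircle(a, b, c):
    ax, ay = a; bx, by = b; cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    r = math.hypot(ax - ux, ay - uy)
    return (ux, uy), r


def brute_force_delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Delaunay edge set by the empty-circumcircle test over all triples.

    Valid for point sets in general position (no 4 cocircular, no 3
    collinear); a triangle belongs to the triangulation iff its circumcircle
    strictly contains no other point.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    if n < 2:
        return set()
    if n == 2:
        return {(0, 1)}
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                cc = _circumcircle(pts[i], pts[j], pts[k])
                if cc is None:
                    continue
                (ux, uy), r = cc
                empty = all(
                    math.hypot(pts[m, 0] - ux, pts[m, 1] - uy) >= r - 1e-9
                    for m in range(n) if m not in (i, j, k)
                )
                if empty:
                    edges.update({(i, j), (i, k), (j, k)})
    return edges


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def union_find_components(n: int, edges) -> list[frozenset[int]]:
    uf = UnionFind(n)
    for a, b in edges:
        uf.union(a, b)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def pr_scan(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float, float]]:
    """All-threshold precision/recall scan (predict positive iff score >= t)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    rows = []
    for t in sorted(set(scores.tolist()), reverse=True):
        tp = fp = 0
        for s, l in zip(scores, labels):
            if s >= t:
                if l == 1:
                    tp += 1
                else:
                    fp += 1
        rows.append((t, tp / (tp + fp), tp / n_pos))
    return rows


def best_threshold_scan(scores, labels, target_recall) -> tuple[float, float]:
    """(threshold, precision): max precision with recall >= target, ties to
    the highest threshold."""
    best = None
    for t, p, r in pr_scan(scores, labels):
        if r >= target_recall and (best is None or p > best[1]):
            best = (t, p)
    return best


def gaussian_window_mean(channel: np.ndarray, sigma: float,
                         truncate: float = 3.0) -> np.ndarray:
    """Direct (non-separable) Gaussian-weighted local average with reflect
    padding, kernel truncated at ±truncate·σ."""
    radius = int(truncate * sigma + 0.5)
    ax = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-ax ** 2 / (2 * sigma ** 2))
    g1 /= g1.sum()
    kernel = np.outer(g1, g1)
    padded = np.pad(channel.astype(float), radius, mode="reflect")
    h, w = channel.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            out[r, c] = np.sum(kernel * padded[r:r + 2 * radius + 1,
                                               c:c + 2 * radius + 1])
    return out
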