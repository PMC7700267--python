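"""Specimen candidate detection from the binary foreground map.

Connected foreground blobs become preliminary candidates: internal holes are
filled (the region enclosed by each blob's external contour is the candidate
segmentation), then candidates smaller than a physical area threshold and
candidates touching the outer 1-pixel frame of the image are discarded —
partially imaged specimens on the field edge are excluded from counting by
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .io import BoundingBox, MicroscopyImage, PipelineConfig, um2_to_px2
from .segmentation import segment_foreground


@dataclass
class Candidate:
    """One detected blob: external-contour segmentation plus summary stats.

    ``mask`` is the hole-filled segmentation restricted to ``bbox`` (local
    coordinates); ``contour`` is the ordered external boundary in global
    (row, col) coordinates; ``centroid`` is the centre of mass (row, col) of
    the filled mask; ``mean_rgb`` is averaged over the filled mask pixels of
    the source image.
    """

    id: int
    contour: np.ndarray
    mask: np.ndarray
    bbox: BoundingBox
    centroid: tuple[float, float]
    area_px: float
    mean_rgb: np.ndarray

    def global_pixels(self) -> set[tuple[int, int]]:
        """The candidate's filled pixels as global (row, col) pairs."""
        rr, cc = np.nonzero(self.mask)
        return set(zip((rr + self.bbox.y_min).tolist(), (cc + self.bbox.x_min).tolist()))


def _external_contour(mask: np.ndarray, y0: int, x0: int) -> np.ndarray:
    """Ordered external boundary of a filled component, global (row, col)."""
    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:  # cannot happen for a non-empty mask
        return np.empty((0, 2))
    longest = max(contours, key=len)
    pts = np.rint(longest).astype(int) - 1  # undo padding, snap to pixels
    pts[:, 0] = np.clip(pts[:, 0], 0, mask.shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, mask.shape[1] - 1)
    # drop consecutive duplicates introduced by rounding
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    return pts + [y0, x0]


def trace_components(mask: np.ndarray, image: MicroscopyImage | None = None) -> list[Candidate]:
    """Extract one candidate per 8-connected foreground component.

    Internal holes are filled first, so each candidate's mask is the region
    enclosed by its external contour; components nested inside another
    component's hole are absorbed by the fill. Candidates are returned in
    raster order of their bounding-box top-left corner, with sequential ids.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {mask.shape}")
    filled = ndi.binary_fill_holes(mask)
    labels = measure.label(filled, connectivity=2)
    cands: list[Candidate] = []
    objects = ndi.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        ys, xs = slc
        local = labels[slc] == lab
        bbox = BoundingBox(xs.start, ys.start, xs.stop, ys.stop)
        rr, cc = np.nonzero(local)
        area = float(local.sum())
        centroid = (float(rr.mean()) + ys.start, float(cc.mean()) + xs.start)
        if image is not None:
            pix = image.pixels[slc][local]
            mean_rgb = pix.reshape(-1, 3).mean(axis=0).astype(float)
        else:
            mean_rgb = np.full(3, np.nan)
        contour = _external_contour(local, ys.start, xs.start)
        cands.append(
            Candidate(0, contour, local, bbox, centroid, area, mean_rgb)
        )
    cands.sort(key=lambda c: (c.bbox.y_min, c.bbox.x_min))
    return [replace(c, id=i) for i, c in enumerate(cands)]


def filter_candidates(
    cands: list[Candidate],
    min_area_um2: float,
    image_shape: tuple[int, int],
    resolution: float,
) -> list[Candidate]:
    """Drop candidates below the physical area threshold or touching the frame.

    The output is a subsequence of the input (no reordering, no mutation):
    a candidate survives iff its filled area is at least ``min_area_um2`` (in
    μm², compared without rounding) and none of its pixels lies on row 0,
    row H−1, column 0 or column W−1.
    """
    h, w = image_shape
    min_area_px = um2_to_px2(min_area_um2, resolution)
    kept = []
    for c in cands:
        if c.area_px < min_area_px:
            continue
        if _touches_frame(c, h, w):
            continue
        kept.append(c)
    return kept


def _touches_frame(c: Candidate, h: int, w: int) -> bool:
    b = c.bbox
    if b.y_min == 0 and c.mask[0, :].any():
        return True
    if b.y_max == h and c.mask[-1, :].any():
        return True
    if b.x_min == 0 and c.mask[:, 0].any():
        return True
    if b.x_max == w and c.mask[:, -1].any():
        return True
    return False


def detect_candidates(image: MicroscopyImage, config: PipelineConfig) -> list[Candidate]:
    """Segment, trace and filter: the full candidate-detection stage."""
    mask = segment_foreground(image, config)
    cands = trace_components(mask, image=image)
    kept = filter_candidates(
        cands, config.min_area_um2, image.shape, image.resolution
    )
    return [replace(c, id=i) for i, c in enumerate(kept)]
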