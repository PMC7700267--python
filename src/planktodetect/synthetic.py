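"""Seeded synthetic bright-field scenes with exact ground truth.

The generator emulates the imaging conditions the pipeline is built for:
a bright, unevenly illuminated background with sensor noise; dark compact
specimens (ellipses); sparse colonies whose cells are visually disconnected
but share a base colour; and debris objects set apart by colour and texture
(speckle instead of the specimens' smooth sinusoidal modulation). Every
rendered object carries a tight ground-truth box, colony membership is
recorded, and scenes are bit-reproducible from their seed.

Placement honours the pipeline's default merge thresholds by construction:
cells of one colony stay within the merge distance of their neighbours with
colour jitter far below the colour threshold, while distinct objects either
lie far apart or differ by more than the colour threshold on at least one
RGB channel — so the planted colony structure is exactly recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw

from .io import BoundingBox, GroundTruthBox, MicroscopyImage

# Base colours (RGB). Any two palette entries differ by >= 70 on at least one
# channel: with per-object jitter of +-5 and a shallow illumination gradient,
# cross-object mean-colour differences always exceed the default 15% colour
# threshold (38.25), and intra-colony differences never do.
SPECIMEN_COLOURS = ((55, 115, 50), (130, 82, 40))
DEBRIS_COLOURS = ((140, 150, 175), (105, 45, 115))

_MARGIN_PX = 12          # object extents stay this far from the frame
_MIN_SEPARATION_PX = 60  # centroid separation between distinct objects
_SAME_COLOUR_SEPARATION_PX = 185  # same-palette objects stay un-mergeable
_CELL_GAP_PX = 4         # free pixels between colony cell rims


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene (lengths in μm unless noted)."""

    size: tuple[int, int] = (512, 512)
    resolution: float = 1.5            # px per μm
    background: float = 235.0
    illumination_amplitude: float = 12.0
    noise_std: float = 3.0
    n_blobs: tuple[int, int] = (2, 4)
    n_colonies: tuple[int, int] = (1, 2)
    n_debris: tuple[int, int] = (1, 3)
    blob_radius_um: tuple[float, float] = (4.0, 12.0)
    colony_cells: tuple[int, int] = (4, 7)
    cell_radius_um: tuple[float, float] = (2.5, 4.5)
    colony_spread_um: float = 45.0     # max cell-centre offset from colony centre
    cell_spacing_um: tuple[float, float] = (12.0, 20.0)  # link length between cells
    colour_jitter: float = 5.0
    texture_freq: float = 0.25         # cycles/px of the specimen modulation
    texture_amp: float = 25.0
    speckle_amp: float = 20.0
    edge_object: bool = False
    seed: int = 0


@dataclass
class SyntheticScene:
    """A rendered scene plus its complete ground truth."""

    image: MicroscopyImage
    truth_boxes: list[GroundTruthBox]
    colony_map: dict[int, list[int]]   # object id -> member blob ids
    label_map: np.ndarray              # H×W object ids (0 = background)
    member_map: np.ndarray             # H×W member blob ids (0 = background)
    edge_object_ids: list[int] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return int(self.member_map.max())


class PackingError(RuntimeError):
    """Raised when the requested objects cannot be placed without conflict."""


@dataclass
class _Member:
    y: float
    x: float
    r: float
    object_id: int
    colour: tuple[int, int, int]


def _separation_ok(members: list[_Member], y: float, x: float, r: float,
                   colour: tuple, object_id: int) -> bool:
    for m in members:
        if m.object_id == object_id:
            continue
        d = math.hypot(m.y - y, m.x - x)
        if d < max(_MIN_SEPARATION_PX, m.r + r + 2 * _CELL_GAP_PX):
            return False
        if m.colour == colour and d < _SAME_COLOUR_SEPARATION_PX:
            return False
    return True


def _colony_offsets(rng: np.random.Generator, spec: SceneSpec,
                    n_cells: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Cell offsets forming a chain of short links inside the spread radius."""
    res = spec.resolution
    spread = spec.colony_spread_um * res
    lo, hi = (s * res for s in spec.cell_spacing_um)
    radii = rng.uniform(*spec.cell_radius_um, size=n_cells) * res
    pos = [(0.0, 0.0)]
    for i in range(1, n_cells):
        for _ in range(60):
            ay, ax = pos[rng.integers(len(pos))]
            ang = rng.uniform(0, 2 * math.pi)
            d = rng.uniform(lo, hi)
            y, x = ay + d * math.sin(ang), ax + d * math.cos(ang)
            if math.hypot(y, x) > spread:
                continue
            if all(math.hypot(y - py, x - px) >= radii[i] + radii[j] + _CELL_GAP_PX
                   for j, (py, px) in enumerate(pos)):
                pos.append((y, x))
                break
        else:
            return None
    return np.array(pos), radii


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one scene; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    res = spec.resolution

    plan: list[dict] = []
    n_blobs = int(rng.integers(spec.n_blobs[0], spec.n_blobs[1] + 1))
    n_colonies = int(rng.integers(spec.n_colonies[0], spec.n_colonies[1] + 1))
    n_debris = int(rng.integers(spec.n_debris[0], spec.n_debris[1] + 1))
    for i in range(n_blobs):
        plan.append({"kind": "blob", "colour": SPECIMEN_COLOURS[i % 2]})
    for i in range(n_colonies):
        plan.append({"kind": "colony", "colour": SPECIMEN_COLOURS[(i + 1) % 2]})
    for i in range(n_debris):
        plan.append({"kind": "debris", "colour": DEBRIS_COLOURS[i % 2]})
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    members: list[_Member] = []
    objects: list[dict] = []
    for obj_id, obj in enumerate(plan, start=1):
        placed = False
        for _ in range(500):
            if obj["kind"] == "colony":
                n_cells = int(rng.integers(spec.colony_cells[0],
                                           spec.colony_cells[1] + 1))
                layout = _colony_offsets(rng, spec, n_cells)
                if layout is None:
                    continue
                offsets, radii = layout
                pad = float(radii.max() + np.abs(offsets).max()) + _MARGIN_PX
                if pad >= h - pad or pad >= w - pad:
                    continue  # colony too large for the frame; retry layout
                cy = rng.uniform(pad, h - pad)
                cx = rng.uniform(pad, w - pad)
                cells = [(cy + oy, cx + ox, r)
                         for (oy, ox), r in zip(offsets, radii)]
            else:
                r = rng.uniform(*spec.blob_radius_um) * res
                if r + _MARGIN_PX >= h - r - _MARGIN_PX \
                        or r + _MARGIN_PX >= w - r - _MARGIN_PX:
                    continue
                cy = rng.uniform(r + _MARGIN_PX, h - r - _MARGIN_PX)
                cx = rng.uniform(r + _MARGIN_PX, w - r - _MARGIN_PX)
                cells = [(cy, cx, r)]
            if all(_separation_ok(members, y, x, r, obj["colour"], obj_id)
                   for y, x, r in cells):
                for y, x, r in cells:
                    members.append(_Member(y, x, r, obj_id, obj["colour"]))
                objects.append({**obj, "cells": cells, "id": obj_id})
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place object {obj_id} ({obj['kind']}) after 500 tries"
            )

    edge_ids: list[int] = []
    if spec.edge_object:
        obj_id = len(objects) + 1
        r = spec.blob_radius_um[1] * res
        side = rng.integers(4)
        if side == 0:
            cy, cx = 0.0, rng.uniform(r + 5, w - r - 5)
        elif side == 1:
            cy, cx = float(h - 1), rng.uniform(r + 5, w - r - 5)
        elif side == 2:
            cy, cx = rng.uniform(r + 5, h - r - 5), 0.0
        else:
            cy, cx = rng.uniform(r + 5, h - r - 5), float(w - 1)
        objects.append({"kind": "blob", "colour": SPECIMEN_COLOURS[0],
                        "cells": [(cy, cx, r)], "id": obj_id})
        edge_ids.append(obj_id)

    # --- render -----------------------------------------------------------
    canvas = np.full((h, w, 3), spec.background, dtype=np.float64)
    label_map = np.zeros((h, w), dtype=np.int32)
    member_map = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    member_id = 0
    for obj in objects:
        jitter = rng.uniform(-spec.colour_jitter, spec.colour_jitter, size=3)
        base = np.asarray(obj["colour"], float) + jitter
        if obj["kind"] in ("blob", "colony"):
            phi = rng.uniform(0, math.pi)
            phase = rng.uniform(0, 2 * math.pi)
            modulation = spec.texture_amp * np.sin(
                2 * math.pi * spec.texture_freq
                * (xx * math.cos(phi) + yy * math.sin(phi)) + phase)
        for y, x, r in obj["cells"]:
            member_id += 1
            if obj["kind"] == "blob" or obj["kind"] == "debris":
                ratio = rng.uniform(0.6, 1.0)
                rot = rng.uniform(0, math.pi)
                rr, cc = draw.ellipse(y, x, r, r * ratio, shape=(h, w),
                                      rotation=rot)
            else:
                rr, cc = draw.disk((y, x), r, shape=(h, w))
            cell_jitter = rng.uniform(-spec.colour_jitter, spec.colour_jitter,
                                      size=3) if obj["kind"] == "colony" else 0.0
            colour = np.clip(base + cell_jitter, 10, 200)
            canvas[rr, cc] = colour
            if obj["kind"] == "debris":
                canvas[rr, cc] += rng.uniform(
                    -spec.speckle_amp, spec.speckle_amp, size=(len(rr), 1))
            else:
                canvas[rr, cc] += modulation[rr, cc][:, None]
            label_map[rr, cc] = obj["id"]
            member_map[rr, cc] = member_id

    # illumination gradient and sensor noise, applied after composition
    ang = rng.uniform(0, 2 * math.pi)
    plane = spec.illumination_amplitude * (
        (xx / w - 0.5) * math.cos(ang) + (yy / h - 0.5) * math.sin(ang))
    canvas += plane[:, :, None]
    canvas += rng.normal(0.0, spec.noise_std, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    image = MicroscopyImage(pixels, spec.resolution, f"scene_{spec.seed}")

    truth: list[GroundTruthBox] = []
    colony_map: dict[int, list[int]] = {}
    mid = 0
    for obj in objects:
        mids = []
        for _ in obj["cells"]:
            mid += 1
            mids.append(mid)
        ys, xs = np.nonzero(np.isin(member_map, mids))
        if len(ys) == 0:  # fully outside the frame (possible for edge objects)
            continue
        box = BoundingBox(int(xs.min()), int(ys.min()),
                          int(xs.max()) + 1, int(ys.max()) + 1)
        label = "other" if obj["kind"] == "debris" else "phytoplankton"
        truth.append(GroundTruthBox(image.image_id, box, label))
        colony_map[obj["id"]] = mids
    return SyntheticScene(image, truth, colony_map, label_map, member_map,
                          edge_object_ids=edge_ids)


def generate_dataset(
    n_images: int,
    spec: SceneSpec | None = None,
    seed: int = 0,
    split: float = 0.5,
) -> tuple[list[SyntheticScene], list[SyntheticScene]]:
    """Generate ``n_images`` scenes with disjoint per-image seeds and split
    them into (train, test) lists.

    Per-image seeds are spawned from one master :class:`numpy.random.SeedSequence`
    so images are mutually distinct yet the whole dataset is reproducible from
    ``seed``. The split assignment is a seeded permutation.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images to split")
    spec = spec or SceneSpec()
    ss = np.random.SeedSequence(seed)
    scene_seeds = [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n_images)]
    scenes = []
    for i, s in enumerate(scene_seeds):
        scene = generate_scene(replace(spec, seed=s))
        img = MicroscopyImage(scene.image.pixels, scene.image.resolution,
                              f"img_{i:03d}")
        truth = [GroundTruthBox(img.image_id, g.box, g.label)
                 for g in scene.truth_boxes]
        scenes.append(replace(scene, image=img, truth_boxes=truth))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_images)
    n_train = int(round(split * n_images))
    train_idx = set(order[:n_train].tolist())
    train = [s for i, s in enumerate(scenes) if i in train_idx]
    test = [s for i, s in enumerate(scenes) if i not in train_idx]
    return train, test


def scenes_annotations(scenes: list[SyntheticScene]) -> list[GroundTruthBox]:
    """Flatten the ground truth of several scenes into one annotation list."""
    return [g for s in scenes for g in s.truth_boxes]
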