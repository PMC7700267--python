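"""Image and annotation I/O, configuration, and physical-unit conversion.

All downstream stages state their thresholds in micrometres; the conversion
to pixels happens here, through a single resolution constant (pixels per μm,
defaulting to 1.5 px/μm, i.e. bright-field imaging at 10× magnification with
a 12 Mpx camera).

Coordinate conventions: pixel indices are 0-based; bounding boxes are
half-open, ``[x_min, x_max) × [y_min, y_max)``, so that
``area = (x_max - x_min) * (y_max - y_min)`` and clamping to the image is
unambiguous. ``x`` indexes columns and ``y`` rows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

VALID_LABELS = ("phytoplankton", "other")

ANNOTATION_COLUMNS = ["image_id", "x_min", "y_min", "x_max", "y_max", "label"]


class ConfigurationError(ValueError):
    """Raised for invalid physical parameters or malformed configuration."""


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation files."""


def um_to_px(length_um: float, resolution: float) -> float:
    """Convert a length in μm to pixels.

    Parameters
    ----------
    length_um
        Non-negative physical length in micrometres.
    resolution
        Imaging resolution in pixels per micrometre (> 0).
    """
    if resolution <= 0:
        raise ConfigurationError(f"resolution must be > 0, got {resolution}")
    if length_um < 0:
        raise ValueError(f"length_um must be >= 0, got {length_um}")
    return float(length_um) * float(resolution)


def um2_to_px2(area_um2: float, resolution: float) -> float:
    """Convert an area in μm² to square pixels (``area × resolution²``)."""
    if resolution <= 0:
        raise ConfigurationError(f"resolution must be > 0, got {resolution}")
    if area_um2 < 0:
        raise ValueError(f"area_um2 must be >= 0, got {area_um2}")
    return float(area_um2) * float(resolution) ** 2


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open box in pixel coordinates."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box ({self.x_min},{self.y_min},{self.x_max},{self.y_max}):"
                " require x_min < x_max and y_min < y_max"
            )

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "BoundingBox") -> int:
        w = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        h = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        return max(w, 0) * max(h, 0)

    def union_with(self, other: "BoundingBox") -> "BoundingBox":
        return BoundingBox(
            min(self.x_min, other.x_min),
            min(self.y_min, other.y_min),
            max(self.x_max, other.x_max),
            max(self.y_max, other.y_max),
        )

    def clamped(self, image_shape: tuple[int, int]) -> "BoundingBox":
        h, w = image_shape
        return BoundingBox(
            max(self.x_min, 0), max(self.y_min, 0),
            min(self.x_max, w), min(self.y_max, h),
        )

    def grown(self, frac: float, image_shape: tuple[int, int]) -> "BoundingBox":
        """Grow the box by ``frac`` of its own width/height on each side.

        Growth amounts are rounded to the nearest integer pixel and the result
        is clamped to the image bounds.
        """
        gx = int(round(frac * self.width))
        gy = int(round(frac * self.height))
        return BoundingBox(
            self.x_min - gx, self.y_min - gy, self.x_max + gx, self.y_max + gy
        ).clamped(image_shape)


@dataclass(frozen=True)
class GroundTruthBox:
    image_id: str
    box: BoundingBox
    label: str

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise AnnotationError(
                f"label {self.label!r} not in {VALID_LABELS}"
            )


@dataclass(frozen=True)
class MicroscopyImage:
    """An 8-bit RGB microscope frame plus its physical resolution."""

    pixels: np.ndarray
    resolution: float
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixel grid, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have H >= 1 and W >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.resolution <= 0:
            raise ConfigurationError(
                f"resolution must be > 0, got {self.resolution}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, i: int) -> np.ndarray:
        return self.pixels[:, :, i]


@dataclass
class PipelineConfig:
    """Tunable physical parameters of the whole detection pipeline.

    Lengths are in μm, areas in μm², fractions are of the 8-bit dynamic range
    (255); conversion to pixels uses ``resolution_px_per_um``.
    """

    threshold_sigma_um: float = 75.0
    threshold_offset_frac: float = 0.08
    min_area_um2: float = 5.0
    merge_distance_um: float = 105.0
    merge_colour_frac: float = 0.15
    bbox_growth_frac: float = 0.10
    resolution_px_per_um: float = 1.5
    rng_seed: int = 0
    # foreground polarity: bright-field specimens absorb light, so they are
    # darker than the local background; "bright" inverts the rule.
    foreground: str = "dark"
    # colony-merging colour rule: per-channel absolute difference ("per_channel")
    # or Euclidean distance in RGB space ("euclidean").
    colour_metric: str = "per_channel"

    def __post_init__(self) -> None:
        for name in ("threshold_sigma_um", "min_area_um2", "merge_distance_um",
                     "resolution_px_per_um"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("threshold_offset_frac", "merge_colour_frac",
                     "bbox_growth_frac"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.foreground not in ("dark", "bright"):
            raise ConfigurationError("foreground must be 'dark' or 'bright'")
        if self.colour_metric not in ("per_channel", "euclidean"):
            raise ConfigurationError(
                "colour_metric must be 'per_channel' or 'euclidean'")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML/JSON config file; keyword overrides win over the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_image(path: str | Path, resolution: float,
               image_id: str | None = None, promote: bool = False) -> MicroscopyImage:
    """Read a PNG/TIFF image as an 8-bit RGB :class:`MicroscopyImage`.

    Grayscale or 16-bit inputs are rejected unless ``promote`` is set, in
    which case grayscale is replicated across channels and 16-bit is linearly
    rescaled to 8-bit.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        if not promote:
            raise ValueError(
                f"{path}: single-channel image; pass promote=True to replicate"
            )
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise ValueError(f"{path}: unsupported image shape {arr.shape}")
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 3 channels, got {arr.shape[2]}")
    if arr.dtype == np.uint16:
        if not promote:
            raise ValueError(f"{path}: 16-bit image; pass promote=True to rescale")
        arr = (arr.astype(np.float64) / 65535.0 * 255.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return MicroscopyImage(arr, resolution, image_id or Path(path).stem)


def save_image(path: str | Path, image: MicroscopyImage) -> None:
    iio.imwrite(path, image.pixels)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 single-channel PNG."""
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_annotations(path: str | Path) -> list[GroundTruthBox]:
    """Read ground-truth boxes from CSV.

    Dialect: header ``image_id,x_min,y_min,x_max,y_max,label``; one record per
    row, order preserved. Raises :class:`AnnotationError` naming the offending
    line for malformed rows, invalid coordinates or labels outside the closed
    {phytoplankton, other} set.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "label": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    out: list[GroundTruthBox] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            coords = [int(getattr(row, c)) for c in ("x_min", "y_min", "x_max", "y_max")]
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"{path}: line {line_no}: bad coordinate ({exc})")
        try:
            box = BoundingBox(*coords)
            out.append(GroundTruthBox(str(row.image_id), box, str(row.label)))
        except (ValueError, AnnotationError) as exc:
            raise AnnotationError(f"{path}: line {line_no}: {exc}")
    return out


def write_annotations(path: str | Path, boxes: Iterable[GroundTruthBox]) -> None:
    rows = [
        {
            "image_id": g.image_id,
            "x_min": g.box.x_min, "y_min": g.box.y_min,
            "x_max": g.box.x_max, "y_max": g.box.y_max,
            "label": g.label,
        }
        for g in boxes
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)
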