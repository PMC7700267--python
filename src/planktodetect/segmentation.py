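"""Foreground/background separation by adaptive Gaussian thresholding.

Each RGB channel is thresholded independently against its Gaussian-weighted
local average minus a fixed offset ``C``, and the three binary maps are fused
with a pixelwise OR. The local averaging window is wide (σ = 75 μm by
default, larger than the target cells) so the threshold tracks uneven
illumination and shading instead of the specimens themselves.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .io import ConfigurationError, MicroscopyImage, PipelineConfig, um_to_px

DYNAMIC_RANGE = 255.0
GAUSS_TRUNCATE = 3.0  # kernel support in units of sigma


def adaptive_gaussian_threshold(
    channel: np.ndarray,
    sigma_um: float,
    offset_frac: float,
    resolution: float,
    foreground: str = "dark",
) -> np.ndarray:
    """Binarise one 8-bit channel against its Gaussian local mean.

    A pixel is foreground iff its value is below (``foreground="dark"``) or
    above (``"bright"``) the Gaussian-weighted local average by more than
    ``C = offset_frac × 255``. The Gaussian spread is ``sigma_um × resolution``
    pixels, the kernel is truncated at ±3σ, and borders are reflected.
    """
    channel = np.asarray(channel)
    if channel.ndim != 2:
        raise ValueError(f"expected a 2-D channel, got shape {channel.shape}")
    if not (0 < offset_frac < 1):
        raise ConfigurationError(f"offset_frac must lie in (0,1), got {offset_frac}")
    sigma_px = um_to_px(sigma_um, resolution)
    if sigma_px < 0.5:
        raise ConfigurationError(
            f"sigma of {sigma_px:.3g} px degenerates the averaging window"
        )
    local_mean = ndi.gaussian_filter(
        channel.astype(np.float64), sigma_px, mode="reflect", truncate=GAUSS_TRUNCATE
    )
    offset = offset_frac * DYNAMIC_RANGE
    if foreground == "dark":
        return channel < local_mean - offset
    if foreground == "bright":
        return channel > local_mean + offset
    raise ConfigurationError("foreground must be 'dark' or 'bright'")


def fuse_channel_masks(*masks: np.ndarray) -> np.ndarray:
    """Pixelwise OR of per-channel masks (same shape required)."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = np.asarray(masks[0]).shape
    fused = np.zeros(shape, dtype=bool)
    for m in masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != shape:
            raise ValueError(f"mask shape mismatch: {m.shape} vs {shape}")
        fused |= m
    return fused


def segment_foreground(image: MicroscopyImage, config: PipelineConfig) -> np.ndarray:
    """Full foreground map: per-channel adaptive thresholds OR-fused."""
    masks = [
        adaptive_gaussian_threshold(
            image.channel(c),
            config.threshold_sigma_um,
            config.threshold_offset_frac,
            image.resolution,
            foreground=config.foreground,
        )
        for c in range(3)
    ]
    return fuse_channel_masks(*masks)
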