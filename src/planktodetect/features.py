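"""Bag-of-visual-words descriptors from colour and Gabor-texture base features.

Colour base features are the raw RGB triples of every pixel inside a
candidate's grown bounding box. Texture base features are the per-pixel
complex responses of a single-scale, multi-orientation Gabor filter bank
applied to the grayscale image (real and imaginary parts interleaved,
``2·No`` values per pixel). Either feature space is quantised against a
k-means dictionary of visual words, and a candidate is described by the
L1-normalised histogram of word assignments over its grown bounding box.

The grown box deliberately includes background pixels: the
foreground/background proportion in the colour histogram acts as an implicit
shape cue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .candidates import Candidate
from .io import MicroscopyImage, PipelineConfig

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

# Subsampling cap for the k-means training pool: clustering cost, not
# dictionary quality, dominates above this many pixels.
MAX_KMEANS_ROWS = 60_000


# ---------------------------------------------------------------------------
# Gabor filter bank
# ---------------------------------------------------------------------------

def gabor_sigma(fc: float, B: float) -> float:
    """Gaussian envelope spread (pixels) for centre frequency ``fc``
    (cycles/pixel) and half-magnitude bandwidth ``B`` (octaves):

        σ = (1 / (π·fc)) · sqrt(ln 2 / 2) · (2**B + 1) / (2**B − 1)
    """
    if fc <= 0 or B <= 0:
        raise ValueError(f"fc and B must be > 0, got fc={fc}, B={B}")
    return (1.0 / (math.pi * fc)) * math.sqrt(math.log(2) / 2.0) \
        * (2.0 ** B + 1.0) / (2.0 ** B - 1.0)


@dataclass
class GaborBank:
    """A single-scale complex Gabor filter bank over No orientations."""

    fc: float
    B: float
    No: int
    sigma: float
    thetas: np.ndarray
    kernels: list[np.ndarray]

    @property
    def radius(self) -> int:
        return (self.kernels[0].shape[0] - 1) // 2


def build_gabor_bank(fc: float, B: float, No: int) -> GaborBank:
    """Realise the complex Gabor kernels on an odd grid covering ±3σ.

    The kernel at orientation θ is
    ``exp(−(x′² + y′²) / (2σ²)) · exp(−j·2π·fc·x′) / (2πσ²)`` with
    ``x′ = x·cosθ + y·sinθ`` and ``y′ = −x·sinθ + y·cosθ``; orientations are
    θ ∈ {0, π/No, …, π(No−1)/No}.
    """
    sigma = gabor_sigma(fc, B)
    radius = int(math.ceil(3.0 * sigma))
    if 2 * radius + 1 < 3:
        raise ValueError(f"sigma={sigma:.3g} px too small for a 3×3 kernel grid")
    y, x = np.mgrid[-radius:radius + 1, -radius:radius + 1].astype(float)
    thetas = np.arange(No) * math.pi / No
    kernels = []
    for theta in thetas:
        xp = x * math.cos(theta) + y * math.sin(theta)
        yp = -x * math.sin(theta) + y * math.cos(theta)
        envelope = np.exp(-(xp ** 2 + yp ** 2) / (2.0 * sigma ** 2))
        carrier = np.exp(-1j * 2.0 * math.pi * fc * xp)
        kernels.append(envelope * carrier / (2.0 * math.pi * sigma ** 2))
    return GaborBank(fc, B, No, sigma, thetas, kernels)


def to_grayscale(image: MicroscopyImage) -> np.ndarray:
    """Luma conversion (0.299 R + 0.587 G + 0.114 B), float64."""
    return image.pixels.astype(np.float64) @ LUMA_WEIGHTS


def texture_responses(image: MicroscopyImage, bank: GaborBank) -> np.ndarray:
    """Whole-image complex filter-bank responses, shape H×W×2No.

    The image is converted to grayscale and convolved (true 2-D convolution,
    reflect borders) with each complex kernel; output channels are ordered
    (real₀, imag₀, real₁, imag₁, …). Computing responses on the whole image
    before cropping avoids boundary aliasing inside the crops.
    """
    gray = to_grayscale(image)
    r = bank.radius
    padded = np.pad(gray, r, mode="reflect")
    out = np.empty(gray.shape + (2 * bank.No,), dtype=np.float64)
    for k, kernel in enumerate(bank.kernels):
        resp = fftconvolve(padded, kernel, mode="valid")
        out[:, :, 2 * k] = resp.real
        out[:, :, 2 * k + 1] = resp.imag
    return out


# ---------------------------------------------------------------------------
# Visual dictionaries
# ---------------------------------------------------------------------------

@dataclass
class BoVWDictionary:
    """k visual-word centroids in colour (d=3) or texture (d=2·No) space."""

    mode: str
    centroids: np.ndarray
    k: int
    feature_scaling: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.k < 2:
            raise ValueError(f"need k >= 2 visual words, got {self.k}")
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count does not match k")


class BoVWVocabulary(BaseEstimator):
    """Sklearn-style estimator learning a k-means visual vocabulary.

    ``fit`` clusters base-feature rows (n×d) into ``k`` words with seeded
    k-means++ (10 restarts, relative inertia tolerance 1e-4); ``transform``
    maps a list of per-region row matrices to L1-normalised word histograms.
    """

    def __init__(self, k: int = 10, mode: str = "colour", seed: int = 0,
                 max_rows: int = MAX_KMEANS_ROWS):
        self.k = k
        self.mode = mode
        self.seed = seed
        self.max_rows = max_rows

    def fit(self, X: np.ndarray, y=None) -> "BoVWVocabulary":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D row matrix")
        if X.shape[0] < self.k:
            raise ValueError(
                f"{X.shape[0]} rows cannot support k={self.k} words; use a smaller k"
            )
        if len(np.unique(X, axis=0)) < self.k:
            raise ValueError(
                f"fewer than k={self.k} distinct rows; dictionary would be degenerate"
            )
        if X.shape[0] > self.max_rows:
            idx = np.random.default_rng(self.seed).choice(
                X.shape[0], self.max_rows, replace=False)
            X = X[idx]
        km = KMeans(n_clusters=self.k, init="k-means++", n_init=10, tol=1e-4,
                    random_state=self.seed)
        km.fit(X)
        self.centroids_ = km.cluster_centers_
        self.dictionary_ = BoVWDictionary(self.mode, self.centroids_, self.k,
                                          seed=self.seed)
        return self

    def transform(self, regions: list[np.ndarray]) -> np.ndarray:
        if not hasattr(self, "centroids_"):
            raise RuntimeError("vocabulary not fitted")
        return np.array([bovw_histogram(r, self.dictionary_) for r in regions])


def build_dictionary(feature_rows: np.ndarray, k: int, seed: int,
                     mode: str = "colour") -> BoVWDictionary:
    """Cluster base-feature rows into a k-word dictionary (seeded k-means)."""
    return BoVWVocabulary(k=k, mode=mode, seed=seed).fit(feature_rows).dictionary_


def bovw_histogram(region_rows: np.ndarray, dictionary: BoVWDictionary) -> np.ndarray:
    """Nearest-centroid histogram of a region's rows, L1-normalised.

    Ties in the Euclidean nearest-centroid assignment break to the lowest
    centroid index.
    """
    rows = np.atleast_2d(np.asarray(region_rows, dtype=float))
    if rows.shape[0] == 0:
        raise ValueError("cannot describe an empty region")
    if rows.shape[1] != dictionary.centroids.shape[1]:
        raise ValueError(
            f"feature dimension {rows.shape[1]} does not match dictionary "
            f"dimension {dictionary.centroids.shape[1]}"
        )
    d = cdist(rows, dictionary.centroids)
    assign = np.argmin(d, axis=1)  # argmin returns the lowest index on ties
    counts = np.bincount(assign, minlength=dictionary.k).astype(float)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Candidate descriptors
# ---------------------------------------------------------------------------

def colour_rows(image: MicroscopyImage, candidate: Candidate,
                growth_frac: float) -> np.ndarray:
    """RGB triples of all pixels in the candidate's grown bounding box."""
    box = candidate.bbox.grown(growth_frac, image.shape)
    crop = image.pixels[box.y_min:box.y_max, box.x_min:box.x_max]
    return crop.reshape(-1, 3).astype(float)


def texture_rows(responses: np.ndarray, candidate: Candidate,
                 growth_frac: float) -> np.ndarray:
    """Precomputed filter-bank response vectors of the grown-box pixels."""
    h, w = responses.shape[:2]
    box = candidate.bbox.grown(growth_frac, (h, w))
    crop = responses[box.y_min:box.y_max, box.x_min:box.x_max]
    return crop.reshape(-1, responses.shape[2])


def extract_descriptor(
    image: MicroscopyImage,
    candidate: Candidate,
    mode: str,
    dicts: dict[str, BoVWDictionary],
    config: PipelineConfig,
    responses: np.ndarray | None = None,
) -> np.ndarray:
    """BoVW descriptor of one candidate's grown bounding box.

    ``mode`` is ``"colour"``, ``"texture"`` or ``"both"``; for texture the
    whole-image response field must be supplied. In ``"both"`` mode the two
    histograms are concatenated and re-normalised to sum to 1.
    """
    frac = config.bbox_growth_frac
    if mode == "colour":
        return bovw_histogram(colour_rows(image, candidate, frac), dicts["colour"])
    if mode == "texture":
        if responses is None:
            raise ValueError("texture mode needs precomputed whole-image responses")
        return bovw_histogram(texture_rows(responses, candidate, frac),
                              dicts["texture"])
    if mode == "both":
        hc = bovw_histogram(colour_rows(image, candidate, frac), dicts["colour"])
        if responses is None:
            raise ValueError("'both' mode needs precomputed whole-image responses")
        ht = bovw_histogram(texture_rows(responses, candidate, frac),
                            dicts["texture"])
        combined = np.concatenate([hc, ht])
        return combined / combined.sum()
    raise ValueError(f"unknown descriptor mode {mode!r}")
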