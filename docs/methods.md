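# Methods

This note documents the models and procedures implemented in
`planktodetect`, the parameter defaults and why they hold, the numerical
choices made where the design was open, and the scope of what the synthetic
study demonstrates.

## Imaging model and units

Input frames are 8-bit RGB bright-field micrographs at a known spatial
resolution in pixels per μm (default 1.5 px/μm, i.e. a 12 Mpx camera on a
10× objective). All physical thresholds are stated in μm or μm² and
converted once, without rounding (75 μm → 112.5 px; 5 μm² → 11.25 px²).
Pixel indices are 0-based; bounding boxes are half-open, so area and
clamping are exact integer arithmetic. Percent-of-dynamic-range parameters
resolve against the dtype maximum (255), not the observed range — an
observed range would make thresholds content-dependent across frames.

## Foreground separation

Each channel is compared against its Gaussian-weighted local average minus
an offset `C`. Defaults: σ = 75 μm (wider than the target cells, so the
local average tracks illumination, not specimens) and `C` = 0.08 × 255 =
20.4, kept fractional. The Gaussian kernel is truncated at ±3σ and borders
are reflected, so frame pixels have a defined local mean. Foreground
polarity is *darker than the local mean*: bright-field specimens absorb
light. The polarity is a config switch (`foreground="bright"`) for other
modalities. σ below 0.5 px is rejected — the averaging window degenerates.
Channel masks are OR-fused, preserving anything any channel detects.

## Candidate detection

Foreground components are taken 8-connected (diagonal cell chains stay
whole) and their internal holes filled, so a candidate's segmentation is the
region enclosed by its external contour; a blob nested inside another blob's
hole is absorbed by the fill. The implementation uses flood-fill labelling
plus morphological hole filling; the external-contour contract is enforced
by an independent flood-fill oracle in the tests rather than by reproducing
any particular border-following algorithm step by step. Candidates below
5 μm² (filled area, measured after hole filling) or with any pixel on the
outer 1-pixel frame are discarded; partially imaged edge specimens are
excluded from counting by convention.

## Colony merging

Candidate centroids are triangulated (Delaunay); an edge survives iff the
centroid distance is ≤ 105 μm *and* the candidates' mean RGB (averaged over
the filled segmentation mask, so background cannot skew it) differs by
≤ 15% of the dynamic range. The colour rule is per-channel — any channel
exceeding 38.25 prunes the edge — because the threshold is defined per RGB
channel; a Euclidean-distance alternative is config-selectable
(`colour_metric="euclidean"`). Surviving connected subgraphs are fused in a
single pass (no re-triangulation): union mask, minimal covering box, and
statistics recomputed from the union. Degenerate centroid sets (n = 2,
collinear points) fall back to the complete graph so the thresholds still
govern merging; duplicate centroids are jittered by 10⁻⁶ px with the
configured seed. Distance is centroid-to-centroid, which is a known
approximation for very large colonies whose centroids can be far apart even
when cells are near.

## BoVW descriptors

A candidate is described over its bounding box grown by 10% of its own
width/height per side (rounded to whole pixels, clamped to the frame).
Background pixels are included deliberately: the foreground/background
proportion of the histogram is an implicit shape cue.

*Colour*: base features are raw RGB triples.
*Texture*: base features are the 2·No per-pixel responses (real and
imaginary parts) of a single-scale complex Gabor bank applied to the
grayscale image (luma weights 0.299/0.587/0.114). The kernel at orientation
θ is `exp(−(x′²+y′²)/(2σ²))·exp(−j2πf_c·x′)/(2πσ²)` on an odd grid covering
±3σ, with θ ∈ {0, π/No, …, π(No−1)/No} and
σ = (1/(πf_c))·√(ln2/2)·(2^B+1)/(2^B−1) for bandwidth B octaves — the
amplitude normalisation gives the envelope unit DC gain; it matches the
scikit-image Gabor kernel, which the tests use as an independent
cross-check. Responses are computed on the whole image before cropping, so
crop boundaries introduce no aliasing; convolution is exact (FFT) with
reflect padding.

Dictionaries are learned by k-means (k-means++ initialisation, 10 restarts,
relative inertia tolerance 10⁻⁴, seeded) over the pooled pixels of all
grown candidate boxes in the training data, both classes included. Pools
larger than 60 000 rows are subsampled with the same seed — beyond that
size clustering cost grows while the dictionary no longer changes
appreciably. Raw responses are clustered (no magnitude normalisation); the
dictionary records its `feature_scaling` so alternatives remain
reproducible. Histograms assign each pixel to its nearest centroid
(Euclidean, ties to the lowest index) and are L1-normalised — box areas
span orders of magnitude, so raw counts would encode size, not appearance.
Combined colour+texture descriptors concatenate the two histograms and
re-normalise to sum to one.

## Classification and model selection

Candidates are labelled positive when their box covers ≥ 50% of some
phytoplankton ground-truth box's area (inclusive). Five classifier families
expose a common real-valued score (higher = more phytoplankton-like):
random forest and kNN via class-1 probability, RBF-SVM and gradient-boosted
trees via their decision function, and a generative option fitting one
diagonal-covariance Gaussian mixture per class and scoring
`log p(x|1) − log p(x|0) + log(π₁/π₀)` with the mixture size as its
hyperparameter.

Model selection is a two-stage grid search under 5-fold stratified
cross-validation (fold assignment is a function of the seed and labels
only). Fitness is the mean across folds of held-out precision at the recall
target (0.90 by default) — preferred over PR-AUC because an operating point
at high recall is what a screening deployment uses. Stage 1 ranks
descriptor configurations (word count; for texture also f_c, B, No) at the
family's default hyperparameters; stage 2 re-searches the classifier
hyperparameters at the stage-1 winner. Ties break to the earliest grid
entry. Visual dictionaries are rebuilt inside each training fold — held-out
pixels never reach dictionary building — and the final dictionary is
rebuilt on the whole training set. The final model stores an operating
threshold: the highest score cut achieving the recall target with maximal
precision on the training scores. Cross-validation splits at candidate
level; image-level grouping is available through the library API by
constructing folds externally.

Default classifier grids (trees × depth for forests and boosting, C × γ for
the SVM, k for kNN, component count for the mixture) are package-defined
defaults recorded in `classify.DEFAULT_CLASSIFIER_GRIDS`.

## Evaluation metrics

A detection matches a ground-truth box when their intersection is ≥ 50% of
the *ground-truth* area (not IoU). FNR is the fraction of phytoplankton
ground-truth boxes with no match; non-phytoplankton objects are excluded
from the FNR because the candidate stage intentionally detects everything.

Oversegmentation counts specimens covered by two or more detections. Under
the strict ≥50%-of-GT association two disjoint detections can never both
cover one specimen, which would pin the rate at ~0 and hide exactly the
failure mode merging exists to fix; the operative definition therefore
associates a detection to a specimen when ≥ 50% of the *detection's* area
lies inside the ground-truth box. Undersegmentation is the fraction of
detections matching ≥ 2 ground-truth boxes under the ≥50%-of-GT rule. Both
denominator conventions (per ground-truth box, per detection) are exposed as
options since the definitions alone do not fix them. PR curves enumerate
every distinct score threshold (predict positive at score ≥ t) and are
verified exactly against an all-threshold scan; precision at recall r is the
maximal precision among thresholds with recall ≥ r.

## Synthetic study

The generator renders 512×512 px scenes at 1.5 px/μm: background level 235
with a random linear illumination gradient (amplitude 12 grey levels) and
additive Gaussian sensor noise (σ = 3, clipped to [0, 255]). Per scene it
plants 2–4 solid elliptical specimens (radius 4–12 μm), 1–2 sparse colonies
(4–7 disk cells of radius 2.5–4.5 μm, chained at 12–20 μm spacing within a
45 μm spread) and 1–3 debris ellipses. Specimens carry a sinusoidal texture
modulation near a Gabor-detectable frequency (0.25 cycles/px, amplitude
25); debris carries uncorrelated speckle — so texture descriptors are
separable by design, echoing the premise that colour and texture
characterise the target organisms. The four palette colours (two greenish /
brownish specimen colours, two grey-blue / purple debris colours) differ
pairwise by ≥ 70 on at least one channel; with jitter ±5 and the gradient,
cross-object colour differences always exceed the 15% merge threshold while
intra-colony differences stay far below it, and objects sharing a palette
colour are placed beyond the merge distance — the planted colony structure
is therefore recoverable by construction. Scenes are deterministic in their
seed; datasets derive per-image seeds from one master `SeedSequence` and
split by a seeded permutation (default 50/50).

Problem sizes: the reference study is 30 images (≈200 candidates, ≈45
colonies); the suite's determinism check uses 6 images with a single-config
grid, since bit-reproducibility does not depend on scale. These sizes keep
the whole study at desk scale while every rate is estimated from a three-digit
candidate count.

**What passing does and does not show.** The synthetic scenes exercise the
full contract of every stage — adaptive thresholding under gradients and
noise, hole filling, edge and area filters, Delaunay pruning and fusion,
descriptor separability, threshold selection, determinism — with exact
ground truth. They do not contain out-of-focus structure, translucent or
touching specimens, physical specimen overlap, debris mimicking specimen
colour, or the long-tailed taxon diversity of real samples; measured rates
(recall ≈ 100%, oversegmentation → 0 after merging, precision ≈ 1) are
therefore upper bounds on real-data behaviour, and the classifier margins
are by construction larger than in field samples. Real deployments should
re-tune σ, C and the merge thresholds on annotated frames from their own
microscope.

## Known limitations

- Merging is single-pass and global; no species-aware thresholds.
- Touching specimens are not split (no watershed): physical overlap is
  accepted as undersegmentation.
- Centroid-based merge distance can under-link very large sparse colonies.
- The GMM family uses diagonal covariances; strongly correlated descriptor
  dimensions are modelled coarsely.
- The CLI `merge` subcommand recomputes detection from the image rather
  than deserialising candidate masks from CSV.
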