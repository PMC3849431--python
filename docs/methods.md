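# Methods

## Problem setting

Dual-probe HER2 FISH slides carry three fluorescence channels per TMA core:
DAPI (all nuclei), rhodamine (HER2 locus, "red") and FITC (CEP17 centromere,
"green"). Clinical scoring counts red and green puncta in tumour nuclei and
classifies each nucleus by the red/green ratio. `fishq` automates this:
nucleus detection on DAPI with a shape-based "ideal nucleus" filter, spot
counting per probe channel, per-nucleus classification, and per-core
aggregation, with an agreement-statistics layer for validating the scorer
against a human rater.

## Image model and pipeline

**Focus fusion.** Scanners record each channel as a short Z-stack (default
5 planes, 0.8 µm apart). Two fusion operators are provided, both
reconstructions — the original acquisition software does not document its
operator:

- `max`: per-pixel maximum. Used for the probe channels: a punctum sharp in
  any plane survives fusion at full amplitude.
- `local_sharpness`: per pixel, take the plane maximizing intensity
  variance in a 9×9 window (window ~ nucleus-border scale: big enough to
  estimate variance stably, small enough to switch planes between
  neighbouring nuclei). Used for DAPI, where maximum projection would stack
  noise and haze from defocused planes onto the nuclear texture.

**Contrast enhancement (DAPI only).** Clip-limited adaptive histogram
equalization, the canonical "locally adaptive contrast enhancement"
(`skimage.exposure.equalize_adapthist`). Profile parameters: `tile_px`
(default 64, ≈ 2–5 nuclei per tile) and `clip` in percent of a tile's pixel
mass per intensity bin (default 2.0 → skimage `clip_limit` 0.02). The probe
channels are deliberately *not* enhanced: equalization is spatially varying
and would distort relative spot intensities before thresholding. Constant
images are returned unchanged; images smaller than one tile fall back to
global equalization with a logged warning.

**Nucleus segmentation.** On the enhanced DAPI plane: Gaussian smoothing
(σ = 2 px) → Otsu threshold → hole filling (chromatin voids would corrupt
area and circularity) → binary opening (disk r = 2). The smoothing and
opening are load-bearing: CLAHE amplifies background noise, and without
them raster borders turn ragged enough to push genuinely round nuclei below
any usable circularity bound, and 1-px noise structures become spurious
candidates. Touching nuclei are split by watershed on the negated Euclidean
distance transform, seeded by h-maxima (h = 2 px) of the distance map;
seeds are labelled with 8-connectivity (diagonal seed pixels on one
distance plateau are one marker — with 4-connectivity a perfect disk can be
halved), and any component without a surviving seed (thin structures) is
seeded at its distance maximum so it remains a single candidate for the
shape filter to reject.

**Ideal-nucleus filter.** Criteria in fixed order (first failure is the
recorded rejection reason): equivalent radius √(area/π) within bounds →
area within bounds → circularity 4π·area/perimeter² ≥ minimum → border
slope ≥ minimum. Border slope is the mean gradient magnitude over the
morphological-gradient band (width ≈ 2 px) of the object, normalized by the
image's dynamic range — it formalizes the steep intensity slope at the
nuclear membrane / marginal chromatin and is invariant to constant offsets.
Objects touching the image border are rejected outright ("border"):
truncated morphology is unmeasurable. A richer radial intensity-template
match would be closer to the "smooth interior profile" idea; the
slope-plus-interior-mean descriptor was chosen as the simplest operator
that separates crisp nuclei from defocused or smeared objects.

**Spot detection.** White top-hat (input minus opening) with a disk whose
radius derives from the spot-size cap, `ceil(√(area_max/π)) + 2`, so any
admissible spot is fully preserved while wider structures are flattened.
The binarization threshold is relative: `threshold ×
P99.9(amplified nonzero intensities)` (default threshold 0.5). Anchoring to
a high percentile makes the cut track slide brightness; it presumes signal
occupies at least ~0.1 % of the field, which holds for cellular TMA cores
but not for a nearly empty field, where the anchor falls into the noise
tail. Components outside the area bounds (default [2, 60] px² at a
40×/0.95 NA-like pixel scale; non-canonical) are dropped; components whose
centroids are closer than `merge_dist_px` (default 2) are merged with their
pixels pooled. No splitting of merged diffraction-limited doublets is
attempted, and a contiguous signal cluster counts as one spot — counts in
heavily amplified nuclei with fused "HER2 cloud" signals are therefore
lower bounds. Spots are assigned to the nucleus label under their rounded
centroid (unambiguous for spots straddling an edge; a spot just outside the
mask is unassigned).

**Classification and aggregation.** With red R and green G per accepted
nucleus: amplified if G ≥ 1 and R/G > `ratio_amplified`; normal if R, G ≥ 1
and R/G within `ratio_normal_band`; artifact otherwise (in particular any
nucleus with a missing probe — its ratio is undefined). `ratio_amplified`
defaults to 2.0, the conventional clinical decision line for the HER2/CEP17
ratio; the literal "ratio above one" reading is one profile edit. The
normal band defaults to [0.8, 1.25], symmetric on the ratio scale, giving
"equal representation" a concrete tolerance. Per core, class counts are
tallied and the normal/amplified split is re-expressed on a 40-cells-per-
core scale (artifacts excluded); with no classifiable nucleus the
standardized fields are absent. A minimum-spots-per-nucleus rule (as in kit
scoring guidelines for evaluable nuclei) is representable by the band/count
rules but not separately enforced.

## Agreement statistics

Cohen's κ = (p_o − p_e)/(1 − p_e) from the contingency table of two raters;
categories with zero marginal under both raters are dropped (avoids 0/0 in
p_e); p_e = 1 is signalled as degenerate. The 95% CI uses the asymptotic
variance of Fleiss, Cohen & Everitt (1969), κ ± 1.96·SE clamped to [−1, 1];
closed-source statistics packages use varying CI constructions, so CI
agreement with other software is approximate even when κ matches exactly.
Spearman's ρ is the Pearson correlation of mid-ranks (tie-aware), CI via
Fisher z with SE = 1/√(n−3), two-sided p from t = ρ√((n−2)/(1−ρ²)) on
df = n − 2 (df is reported alongside ρ, as agreement tables conventionally
do). Verbal interpretation follows Landis & Koch: < 0 poor, ≤ 0.20 slight,
≤ 0.40 fair, ≤ 0.60 moderate, ≤ 0.80 substantial, ≤ 1 almost perfect.
Weighted κ, multi-rater κ and bootstrap CIs are out of scope.

## Synthetic cores

The simulator renders exactly the structure the detector assumes, which is
what makes it a sharp unit- and recovery-test instrument and *not* evidence
about clinical images:

- **Nuclei**: discs with a flat interior plateau and a sigmoidal border
  falloff (width 1.5 px), radius uniform in [12, 16] px, placed on a
  randomly jittered grid guaranteeing centre separation ≥ 3 × max radius.
  Deterministic class allocation: exactly `round(n·amplified_frac)` nuclei
  are amplified, so recovery tests have exact expectations.
- **Spots**: isotropic 2-D Gaussians (σ = 1.5 px) planted inside the inner
  80 % of each nucleus radius; normal nuclei get 2 red / 2 green, amplified
  nuclei draw red from [6, 9] with 2 green. Within one channel of one
  nucleus, spots keep ≥ 6 px separation: two σ = 1.5 Gaussians closer than
  about 4σ remain above any usable threshold along the segment joining
  them, so a connected-component detector without doublet splitting cannot
  resolve them even noise-free; 6 px ≈ 4σ is the resolvability limit of
  the prescribed detector.
- **Optics and noise**: each nucleus (with its spots) is sharp in one
  randomly chosen plane and Gaussian-blurred elsewhere in proportion to
  plane distance (defocus σ = 2 px per plane step); additive Gaussian
  camera noise with σ = amplitude/SNR, default SNR 10 — equivalently a
  noise σ of 5 % of the dynamic range at the default amplitude (0.5 of
  range above a 0.05 background). Output is quantized to 16-bit.
- One seeded generator drives everything; a seed fixes the output
  byte-for-byte.

Not emulated: tissue autofluorescence texture, vignetting/shading, nuclear
pleomorphism and crowding beyond the separation rule, fused signal
clusters, photobleaching, chromatic shift. Passing recovery tests therefore
demonstrates the algorithm is correct under its own image model, not that
it meets any accuracy level on patient material.

## Numerical and interface choices

- Coordinates are 0-based (row, col); bounding boxes half-open; circularity
  is clamped at 1.0 (raster perimeters can slightly undershoot the
  continuous value).
- Image I/O is plain single/multi-page grayscale TIFF (8/16-bit), one file
  per channel, one page per focus plane — the lossless common denominator;
  proprietary slide formats are out of scope. Reads are bit-exact.
- The MISP profile XML and the results XML are newly designed minimal
  schemas (the tool this package descends from never published its file
  schemas); the results schema ships as an XSD, unknown profile elements
  are ignored with a warning for forward compatibility, and serialization
  uses `repr` round-tripping so profiles survive write→read without loss.
- Default problem sizes in tests and the acceptance script (512² px cores,
  40 nuclei, 10–20 seeded replicates) were chosen as the smallest scenes
  that exercise crowding, the fraction sweep and both probe channels while
  keeping a full suite run in tens of seconds.

## Known limitations

Nucleus splitting assumes near-convex nuclei (distance-transform
watershed); the spot-count ceiling for fused clusters biases heavily
amplified nuclei downward; the percentile threshold anchor needs a
minimally populated field; CI formulas are asymptotic and degrade for very
small n; no 3-D segmentation or sub-pixel spot localization.
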