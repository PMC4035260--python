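# Methods

## Model and assumptions

The pipeline treats palm-vein verification as sparse keypoint
correspondence. Its assumptions, stage by stage:

* **Segmentation** assumes a bimodal intensity histogram: a bright hand on
  a dark background, as produced by NIR reflectance imaging. Otsu's
  threshold is computed over the whole frame; classes are `intensity <= t`
  vs `> t` and the foreground is the upper class. Ties in the between-class
  variance are broken toward the smallest maximizing threshold. The
  wrist crop assumes the palm-plus-fingers silhouette is radially bounded
  around its centroid while the forearm extends beyond; it is a pure
  radial cut, with no landmark detection.
* **Enhancement** assumes veins live in a known spatial-frequency band.
  The DoG pair (σ₁ = 2 px, σ₂/σ₁ = 1.6) passes structures a few pixels
  wide; anything much smoother (illumination) or much finer (pixel noise)
  is attenuated. Histogram equalization assumes relative intensity order,
  not absolute level, carries the vein information: it is a monotone map
  estimated from mask pixels only, so the black background cannot skew the
  CDF.
* **Matching** assumes descriptor similarity between genuine samples under
  moderate pose change — SIFT's invariance envelope. RootSIFT replaces
  Euclidean comparison with the Hellinger kernel on L1-normalized
  descriptors; the transform v ↦ √(v/Σv) makes every downstream Euclidean
  computation realize that kernel exactly.
* **Mismatch removal** assumes genuine pose change is approximately a
  similarity transform: centroid-relative coordinates cancel translation
  exactly and (with radius normalization) isotropic scale, so large
  relative displacement flags a mismatch. The LBP layer assumes the local
  micro-texture around a genuinely corresponding point pair is stable
  enough that their uniform-LBP histograms stay close.
* **Verification** assumes the surviving match count is monotone in
  identity likelihood; FAR/FRR are swept over the integer score range and
  the EER is found by linear interpolation of the discrete crossing
  (scores are small integers; the step curves rarely intersect at a grid
  point).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `crop_factor` | 1.8 | palm equivalent radii | keeps fingers of a typical hand silhouette, cuts forearm beyond ~1.8·√(area/π) |
| `dog_sigma` (σ₁) | 2.0 | px | matches synthetic vein half-widths (veins 2–4 px wide at the 256² reference resolution) |
| `dog_ratio` (σ₂/σ₁) | 1.6 | — | classical LoG-approximation ratio for band-pass detail enhancement |
| `he_scope` | mask_only | — | background zeros would dominate a full-frame CDF |
| `dist_ratio` | 0.8 | — | Lowe's ratio-test threshold; sweeps between 0.6 and 0.9 change totals by a few percent without changing orderings |
| `neighbor.distance_threshold` | 0.35 | palm radii | calibrated, see below |
| `neighbor.scale_normalize` | true | — | cancels isotropic scale between samples; pixel-unit mode retained |
| `lbp.patch_size` | 32 | px | (32−2)² = 900 codes per histogram — enough mass for 59 bins, still local |
| `lbp.distance_threshold` | 200 | chi-square units (mass 900) | calibrated, see below |
| `lbp.distance_kind` | chi_square | — | symmetric, zero iff equal, standard for LBP histograms; `l1` and `intersection` selectable |

### Threshold calibration

The two mismatch-removal thresholds have no principled closed form, so
they were fixed once by calibration on a synthetic fixture set (6
identities × 4 posture samples, master seed 987654 — disjoint from the
benchmark seed used in tests) with ground-truth correspondence labels at
3 px reprojection tolerance. Both defaults sit at the equal point of
true-match retention vs false-match removal, subject to not degrading the
fixture-set EER relative to unfiltered scoring. The neighbor threshold
deserves a note: under an in-plane rotation difference Δθ between two
samples, a *correct* correspondence at normalized radius ρ shows a
relative-coordinate displacement of 2·sin(Δθ/2)·ρ — about 0.5 palm radii
for a fingertip point under the ±15° posture pair. A tight threshold
(e.g. 0.25) therefore removes a large share of genuine correspondences on
rotated pairs; 0.35 balances the two error types. This rotation
sensitivity is intrinsic to the neighbor criterion, which models pose as
translation + scale only.

## The synthetic generator

Each identity is a hand-shaped polygon (palm disk, four fingers and a
thumb as capsules, and a forearm stub running off the frame so the wrist
crop has something to cut) carrying a random branching vein tree grown by
a rejection-sampled random walk confined to the silhouette. The canonical
render places the hand at ~160–185 intensity on a ~10 background with
veins 35 units darker, plus an identity-locked smooth texture field
(Gaussian random field, σ = 3.5 px, amplitude 10–14) emulating the stable
mottle of real palm skin. That field matters: without stable micro-texture
the region between veins would carry only per-sample noise, uncorrelated
between genuine samples, and patch-texture consistency (the LBP layer's
premise) would be untestable.

A sample applies, in order: a projective warp (rotation and isotropic
scale about the frame centre, translation, and a perspective
foreshortening term parameterized in degrees of hand tilt), a
multiplicative illumination ramp whose amplitude fraction is measured
across the hand's own extent, Gaussian blur, and additive Gaussian noise.
Galleries draw samples from six posture archetypes — scale 0.8 / 1.2,
in-plane tilt ±15°, perspective tilt ±10°, each with small jitter,
translation ±8 px, illumination 0.15–0.35, blur 0.8–1.2 px, noise 3–5
intensity units. Every artifact is a pure function of integer seeds
(bit-identical regeneration), every sample records its exact forward
homography, and genuine pairs share vein topology while impostor pairs
never do.

What the generator does **not** emulate: photorealistic NIR radiometry
(skin scattering, hemoglobin absorption spectra, sensor vignetting),
non-rigid articulation (finger pose changes between samples), specular
artifacts, and population-level correlation between different hands' vein
topologies. Passing tests therefore demonstrate the pipeline's mechanics
and its behaviour under controlled geometric/photometric nuisance, not
field performance on real palms.

## Numerical choices

* DoG kernels are exact samples of the continuous Gaussian (no
  re-normalization), truncated at 6σ where the density is < 1e-9, applied
  separably with reflective padding; the impulse response equals the
  analytic kernel to float precision and the constant-image response is
  numerically zero.
* The signed DoG response is rescaled to [0, 255] by its min/max over mask
  pixels; a flat response maps to 128.
* Equalization uses `round(255·CDF)` with the CDF over mask pixels.
* Ratio-test ties: the second-nearest neighbour is chosen by stable sort
  (smallest index); duplicate gallery descriptors at distance 0 define the
  ratio as 1 (reject), avoiding division by zero.
* LBP: s(0) = 1 (ties count as ≥), bits ordered clockwise from the
  top-left neighbour; 58 uniform patterns (≤ 2 circular transitions) get
  individual bins in ascending code order, all others share bin 58.
  Match patches are taken from the *enhanced* image (the matching
  substrate); pairs whose patch exits the image are removed conservatively
  with a logged reason.
* Unsegmentable images raise; in gallery evaluation their comparisons are
  missing, never scored 0.
* The all-pairs protocol scores each unordered pair once; a
  first-sample-enrollment protocol is available as an alternative.

## Problem sizes

The standard benchmark is 20 identities × 4 samples (3160 scored pairs,
~70k ground-truth-labelled candidate matches) at 256×256 resolution — large
enough for stable EER and retention/removal estimates, small enough to run
in well under a minute per pass on one CPU. The descriptor robustness
sweep uses one identity, digitally rotated {0,5,10,15,20}° and rescaled
{0.8–1.2×} as in the classical comparison protocol.

## Known limitations

* The neighbor filter penalizes genuine correspondences under in-plane
  rotation (see calibration note); under the ±15° posture archetypes the
  joint operating ceiling of the two filters is ~75% true retention at
  ~75% false removal — raising one beyond 80% necessarily drops the other.
  The filters nonetheless improve verification: they shrink impostor
  scores by a much larger factor than genuine scores.
* On this synthetic data RootSIFT and plain SIFT ratio-test counts differ
  by at most a couple of matches in either direction: the detector's
  standard gradient clipping plus the generator's relatively unambiguous
  texture leave the Hellinger reweighting few decisions to change. A
  systematic RootSIFT advantage should not be expected from the synthetic
  sweeps, only parity.
* Histogram equalization amplifies residual noise in texture-poor regions;
  scoring a palm against a noise blob can yield one or two chance matches.
* The radial wrist crop assumes the forearm extends beyond the palm's
  radial envelope; for hands imaged with almost no visible forearm the
  crop is a no-op (harmless), and for extreme croppings it can clip
  fingertips.
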