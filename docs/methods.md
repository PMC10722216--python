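# Methods

This note documents the models, parameters and numerical choices behind
`ttmorph`, and what the synthetic-data tests do and do not establish about
real data.

## Cell preparation (geometry)

The long axis of a cell mask is the major eigenvector of the second central
moments of its foreground coordinates; the angle is reported
counter-clockwise from the vertical image axis in (−90°, 90°]. Equal
eigenvalues (an isotropic mask) are a degenerate case and resolve to 0°
(no rotation), with a flag. Rotation uses bilinear interpolation for all
channels and for the mask, which is re-binarised at 0.5; the result is
cropped to the mask bounding box plus a 10 px margin (configurable — real
crops may or may not retain extracellular WGA signal near the cell).

Quality control makes the usual manual exclusion criteria deterministic,
each with a config-exposed threshold:

| check | statistic | default |
|---|---|---|
| low contrast | (p99 − p1)/p99 of in-mask WGA intensity | ≥ 0.2 |
| curvature | mask area / bounding-box area after rotation | ≥ 0.75 |
| inconsistent labelling | CV of per-sarcomere-band mean intensity | ≤ 0.6 |
| edge contact | mask touches the crop frame | fail |

Edge contact after bounding-box cropping with a margin implies the cell
touched the source field border (the margin cannot extend past the frame).

## Segmentation (segment)

Binary tubule masks are an explicit interchange point: masks exported from
an interactive pixel classifier can be loaded (any nonzero pixel = tubule,
intersected with the cell mask), and the pipeline is agnostic to their
origin. The built-in baseline segmenter is purely classical and
deterministic: white top-hat (radius 3× the expected tubule width) →
Gaussian smoothing (σ = 1 px) → Otsu threshold within the cell mask →
removal of components < 9 px → exclusion of a 3 px peripheral rim (the
surface sarcolemma is not a t-tubule) and of nucleus-scale intensity voids
(large connected regions of the heavily smoothed WGA image below half the
in-cell median). Otsu always splits a histogram, so a class-separation
guard ((μ₁ − μ₀)/σ₀ ≥ 4) returns an empty mask on structure-free input;
splitting unimodal noise yields a separation of only ≈ 2.5.

Interactive pixel classification itself is deliberately not reimplemented:
the contribution of this package is the downstream morphometry.

## Sarcomeric regularity (regularity)

The image (binary mask for T-power; raw RyR restricted to the cell, with
outside-mask pixels set to the in-mask mean, for R-power) is
mean-subtracted, tapered with a 2-D Hann window, zero-padded to a 512 px
square (grown if the cell is larger), and Fourier transformed. The profile
is the power along the longitudinal-frequency axis through the origin,
averaged over a 3-bin transverse band, normalised by total power and
expressed in dB; the first 100 bins from DC are kept. Normalisation plus
the dB scale makes scores invariant to global intensity scaling and
translation.

The first harmonic is fitted as Gaussian + linear baseline over the search
band 1/2.4–1/1.5 µm⁻¹ (physiological sarcomere spacing); the score is the
fitted height above baseline in dB. Robustness constraints: amplitude
bounded by 2.5× the profile's dynamic range in the band and the centre kept
off the band edges — an unbounded fit can otherwise park an arbitrarily
tall Gaussian at a boundary against a runaway baseline. Failed or
non-positive fits score 0 with `fit_ok=False` rather than being dropped, so
cells with destroyed lattices remain in the statistics. Window and padding
affect absolute peak heights, so scores are comparable within a
configuration only; no attempt is made to reproduce any particular
historical instrument's arbitrary units.

## Morphometry

* **Area %** = 100 · |tubule mask| / |cell mask|.
* **Length %** = 100 · (skeleton pixel count) / |cell mask|. The skeleton
  is Zhang-style topology-preserving thinning; length is the plain pixel
  count (keeping length % ≤ area % an exact identity). A √2 diagonal
  correction is available behind a config flag for sensitivity analysis.
* **Transverse %**: each skeleton pixel gets a local orientation — the
  chord of the farthest-apart pair of pixels within a geodesic ball of
  radius ⌊window/2⌋ (window 7 px ≈ 0.6 µm) along the skeleton. On a simple
  branch this equals the chord between the pixels half a window away in
  each direction; at branch points the deepest-reaching arms win, i.e. the
  orientation of the longest incident branches; ties break toward the
  smaller angle. The geodesic-ball form was chosen over a neighbour-walk
  because digital lines with diagonal shortcuts otherwise masquerade as
  branch points. Transverse elements are pixels with orientation in
  [60°, 130°] from the vertical (longitudinal) axis, implemented literally
  and inclusive at both ends; the asymmetry about 90° is kept as the
  field's stated definition, without interpretation. An empty skeleton
  reports a missing value, not 0.
* **Thickness ratio** = |mask| / skeleton pixel count — a mean tubule width
  proxy in pixels (missing if the skeleton is empty).

All internal lengths are in pixels; physical units enter only through the
pixel size (85 nm default) at reporting time.

## Optics

Lateral resolution is Rayleigh's 0.61 λ/NA (0.51 and 0.37 prefactors are
available for confocal-specific conventions); with 618 nm emission and
NA 1.4 this gives 269.3 nm. The Nyquist-limiting pixel is half the
resolution (≈ 134.6 nm), boundary inclusive; an 85 nm pixel passes.

## Synthetic data (simulate)

The generator emulates what the pipeline consumes, not tissue biology:

* Cell: superellipse (exponent 4) mask, aspect ≈ 4, default 384 × 96 px
  (≈ 33 × 8 µm at 85 nm/px) — a desk-scale crop; the long-cell variant
  768 × 192 px is used where sweep statistics need more z-lines.
* Lattice: transverse centerlines at the sarcomere period (default 1.9 µm,
  typical rat ventricle), each line shifted by N(0, jitter²) (default
  jitter 0.05 µm); one contiguous run per line covering the fraction of
  the row needed for the area budget, plus vertical axial connectors
  between adjacent z-lines up to the axial fraction (default 0.3 of
  centerline length). Long runs keep skeleton end-retraction negligible, so
  the realised thickness tracks the drawn width.
* Width/area: centerlines are thickened to the drawn width (default 5 px);
  a few budget top-up passes compensate junction overlap so the realised
  mask area matches the target fraction (default 0.265) to ≈ 0.3 %.
  The default width is chosen so that drawn centerline geometry stays
  resolvable after thinning; classifier masks of real confocal data are
  typically wider (thickness ratios near 9 px), which rescales length %
  and thickness but not the group contrasts the pipeline is about.
* Imaging: WGA = mask + cell outline, RyR = puncta along the z-lines
  (0.6 µm spacing, 0.05 µm positional jitter), both convolved with an
  isotropic Gaussian PSF (FWHM 270 nm; an Airy model adds nothing at this
  scale), then Poisson photon noise (peak ≈ 100 photons, 8 % background)
  and Gaussian read noise (σ = 1.5 counts).
* Designs: group × animal × region × cell with per-animal Gaussian random
  intercepts on generating parameters (default SD 0.015 on area fraction)
  and fixed (group, region) overrides. The `infarct_effects` preset encodes
  a border-zone loss of tubule area (26.5 % → 15.9 %, partially restored
  to 21 % under treatment) with matching jitter/axial shifts — a
  demonstration preset, not a claim of reproducing any animal data.
* Determinism: every realisation is a pure function of (parameters, seed).

For statistical calibration and power studies, `generate_metric_table`
draws per-cell metric values directly from the same hierarchical model
(base + fixed effect + animal intercept + cell noise) without rendering
images; rendering would only add the imaging-recovery error already
characterised separately.

What passing recovery tests show: the pipeline correctly measures what the
generator draws (straight jittered lattices under Gaussian blur and
Poisson noise). What they do not show: performance on curved or
partially-sectioned cells, anisotropic PSFs, labelling gradients, scar
tissue, or classifier-specific mask biases — real-data conclusions still
require the QC step and an externally validated segmentation.

## Statistics (stats)

Per metric: linear mixed model with cell-means coding of the group × region
strata and a random intercept per animal, fitted by REML (statsmodels).
Pairwise stratum contrasts are Wald t tests; degrees of freedom use a
between–within approximation — contrasts between strata sharing no animals
use (number of animals − number of groups), within-animal contrasts use
(N − animals − strata + groups). Families are counted per metric × region
(all pairwise group comparisons within a region); region contrasts within
a group (e.g. border zone vs remote LV) are exposed separately with their
own family. Multiplicity uses Dunn–Šidák, p′ = 1 − (1 − p)^m, clipped to 1.
Groups with fewer than two animals are rejected (the between-animal
contrast would have no degrees of freedom). Random slopes and exact
emulation of any particular commercial df method are out of scope; at the
package's problem sizes the calibration simulations show the adjusted
false-positive rate is controlled (if anything conservative).

## Problem sizes and tolerances

Default test and acceptance problem sizes are desk-scale by design:
50 cells for recovery, 6-level sweeps with 3 replicates, 200 simulated
studies (3 groups × 4 animals × 10 cells) for calibration, 50 replicates
for power. Recovery tolerances (mean absolute error ≤ 2 area points,
≤ 5 transverse points, ≤ 0.5 px thickness, peak frequency within one
512-pad FFT bin) reflect the discretisation limits of the generator and
the rotation/binarisation steps, not fitted constants.

## Known limitations

* Single 2-D confocal planes only; no z-stacks or 3-D tubule topology.
* Cells are user- or fixture-delimited crops; no whole-field detection.
* The baseline segmenter is a stand-in for trained pixel classification
  and is tuned for the synthetic contrast regime.
* Skeleton-based length underestimates true geodesic length by up to √2
  on diagonals (flag available); thickness is a confocal-blurred proxy,
  not a nanoscale diameter.
* The transverse orientation of skeleton pixels near junctions inherits
  the longest incident branch, which slightly inflates transverse % on
  dense lattices (≈ 3 points at default conditions, well inside the
  stated recovery tolerance).
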