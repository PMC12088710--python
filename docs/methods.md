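# Methods

This note records the measurement conventions, parameter defaults and
design choices behind `octquant`, and what the phantom-based tests do and
do not demonstrate.

## Geometry and ray casting

Frames are 2D integer label maps over the ten-class coronary OCT schema
with isotropic pixel spacing (anisotropic inputs are rejected at load
time). Pixel coordinates are `(row, col)` with pixel centers at integer
positions; angles run counterclockwise from the +column axis. All arc
magnitudes are rotation invariant, so the angular origin is purely an
internal convention.

The ray-cast origin is the arithmetic-mean centroid of the **largest
connected lumen component**, so stray mislabelled lumen pixels cannot
drag the origin; by default the centroid is taken after
connected-component cleanup (the CLI applies post-processing before
quantification; library users may order the steps freely).

`cast_rays` samples labels by nearest-neighbour lookup every 0.25 px
from the origin to the frame edge and merges equal consecutive samples
into radial intervals whose bounds lie at inter-sample midpoints.
Nearest-neighbour lookup avoids interpolating categorical labels; the
quarter-pixel step keeps interval-boundary quantization well below the
pixel scale while staying cheap (a 720-ray cast of a 896² frame takes
well under a second). Intervals tile each ray without gaps.

Default `n_rays = 720` (0.5° bins). An angular bin is plaque-positive
iff its ray contains the class anywhere; sectors are maximal circular
runs of positive bins.

## Guidewire handling

The guidewire shadow destroys the wall signal behind it. Following
standard reading practice, a plaque visible on both sides of the shadow
is measured continuously across it: a maximal run of shadowed rays
immediately flanked on both sides by plaque-positive rays is absorbed
into one *bridged* sector. Bridged spans count toward the arc but
contribute nothing to cap area, minimum FCT, calcium depth or thickness
— no tissue pixels exist behind the shadow, and rays through the shadow
are excluded from radial measurements.

## Radial measures

Minimum FCT and calcium depth are radial-gap measures along centroid
rays: on each qualifying ray, the radial start of the first plaque
interval minus the radial end of the lumen interval; the minimum over
rays is reported in µm. A Euclidean-distance-transform variant
(`fct_mode="edt"`: shortest distance from any plaque pixel to the lumen
mask) is exposed for sensitivity analysis; on concentric geometry the
two agree to within discretization. Calcium thickness is the maximum
over rays of the summed radial extent of calcium intervals. When a
plaque class occupies several sectors, minima/maxima are taken over the
union (the cumulative convention also used for arcs and cap areas).

The fibrous cap area counts intima pixels whose angle falls in a
non-bridged lipid-positive bin, times the pixel area; the cap ratio
divides it by the lipid arc. The lipid-rich-plaque flag is inclusive at
exactly 90°.

## Post-processing

Connected components use 8-connectivity. The minimum-area threshold is
expressed in mm² (default 0.005 mm², ≈50 px at 10 µm pixels) so it is
resolution independent. Sub-threshold components are relabelled to the
modal class of their 8-neighbour border (background on ties), which
preserves wall contiguity instead of punching holes; thrombus and
plaque rupture are exempt because their smallest true instances matter
clinically, and background is never filtered. Passes repeat to a fixed
point, making the filter idempotent; if majority relabelling fails to
stabilise within a few passes (possible only for adversarial label
arrangements), remaining small components are relabelled to background,
which strictly shrinks the filtered classes and must terminate.

## Agreement statistics

- Proportions (accuracy, sensitivity, specificity, PPV, NPV) carry exact
  Clopper–Pearson 95% intervals via beta quantiles; the exact method is
  used because frame counts per class can be very small.
- Cohen's κ uses the standard 2×2 definition; its Wald CI uses the
  large-sample (Fleiss–Cohen–Everitt) standard error.
- The ICC is fixed to single-measures two-way-random absolute agreement,
  ICC(2,1), from the two-way ANOVA mean squares, with the McGraw–Wong
  F-based interval (cross-checked in the tests against `pingouin`);
  single measures is the natural choice for per-frame comparisons of one
  prediction against one reference.
- Bland–Altman differences are prediction − reference; limits are
  mean ± 1.96 SD.
- Per-frame Dice: FP/FN frames score 0; TN frames carry no score and are
  excluded from all Dice aggregation while still entering confusion
  tables and κ. Aggregation is reported over TP∪FP∪FN and over TP only.
- External-test consensus: evaluation is restricted to frames where both
  observers agree on presence/absence; for continuous measures the
  observer mean is the reference.

## Phantom generator

The phantom renders what the quantification consumes — label maps, not
OCT signal. Concentric anatomy (lumen disc, intima annulus, media
annulus) is drawn around a configurable centre; each plaque sector
replaces the wall with cap intima from the lumen border to
`lumen_radius + cap_thickness` and plaque tissue for
`plaque_thickness` beyond it, with the media interrupted behind the
plaque (mimicking attenuation). The guidewire wedge overwrites
everything outside the lumen; a side-branch wedge replaces wall labels.
Speckle blobs of exact pixel count are placed on background by seeded
rejection sampling, ≥5 px from all structures, and are strictly smaller
than the default cleanup threshold.

Default rendering is a 896×896 grid at 5 µm/px (4.48 mm field of view).
The randomized-phantom generator draws lumen radius 0.9–1.2 mm, baseline
intima 0.2–0.3 mm, media 0.1–0.18 mm, fibrous caps 0.12–0.25 mm, plaque
thickness 0.3–0.5 mm and sector arcs 45–80°, assigning angular features
to distinct quadrants so same-class sectors never overlap and wedges
never touch plaque. These ranges describe a diseased but unoccluded
coronary segment at OCT resolution.

The phantom does **not** emulate OCT intensities, speckle texture,
attenuation-limited abluminal borders, eccentric or non-circular lumina,
or inter-frame motion. Parameter-recovery results on phantoms therefore
demonstrate the correctness of the geometry and measurement code, not
segmentation performance on clinical images.

## Numerical tolerances

With the defaults above, measured metrics recover the closed-form
phantom values within: arcs ±1° (0.5° binning plus sub-pixel
rasterization fuzz at sector edges), radial measures ±1.5 px, cap areas
±3% (angular-edge fuzz multiplied by the intima/cap thickness ratio).
The recovery suite checks 50 seeded random phantoms plus rotation
(quarter-turn) and whole-pixel translation invariance in about half a
minute on one CPU.

## Degenerate inputs and tie-breaks

Frames without lumen raise `NoLumenError`; label codes outside 0..9 are
reported by `validate_frame` and rejected by the readers. A
correspondence score with both arcs empty is undefined
(`UndefinedScoreError`), as is the cap ratio at zero arc
(`ZeroArcError`) and any proportion with a zero denominator. Border
majority ties in the cleanup filter resolve to background. Stacked
pseudo-3D input windows replicate edge frames.
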