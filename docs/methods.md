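# Methods

This note documents the models implemented in `tumourtrace`, the defaults
and why they were chosen, what the synthetic plates do and do not emulate,
and the numerical decisions that affect results.

## Imaging model and synthetic plates

A well is imaged as a Z-stack of grayscale planes. The simulator
(`tumourtrace.simulate`) renders tumouroids as dark, anti-aliased disks on a
bright background; each object sits at one focal plane and appears on other
planes blurred by an isotropic Gaussian PSF whose sigma grows linearly with
defocus distance (`blur_per_um_defocus`, default 0.04 px/µm with 50 µm plane
spacing, i.e. 2 px of blur per plane step). Overlapping objects combine by
maximum attenuation, so intensities stay within
[`object_level`, `background_level`] before additive Gaussian noise.

Default scenario (one plate = one biological sample):

| parameter | default | rationale |
|---|---|---|
| image size / pixel size | 512×512 px at 2 µm/px | ~1 mm field, low-magnification screening |
| Z-planes / spacing | 5 planes, 50 µm | objects distributed through a gel droplet |
| objects per well | 20 | moderate seeding density |
| day-0 radius | uniform 25–80 µm | the 40–200 µm diameter seeding fraction |
| growth rate g | 0.08 /day (radius) | ~3× radius, ~8× area over 14 days — within the range a two-week screen shows |
| doses | 0 (vehicle), 0.1, 1, 10, 100, 1000 nM | 5-step, 10-fold ladder plus solvent control |
| replicates | 4 | technical replicates per condition |
| treatment window | day 2, for 7 days | drugging starts 2 days after seeding and is washed out after a week |
| intensities | background 0.85, objects 0.35, noise sd 0.01 | mid-contrast brightfield appearance |

Growth is exponential in radius, r(t) = r₀·exp(g·t). Drug exposure at
concentration x scales the rate by (1 − i(x)) during the exposure window,
with Hill inhibition i(x) = xʰ/(xʰ + IC50ʰ) (defaults h = 1, IC50 = 10 nM).
This is a deliberate stand-in: no quantitative growth law for patient
tumouroids is assumed, only the qualitative features the pipeline must
recover — monotone dose effect, vehicle growth, and a mid-ladder potency.

Wells of the same replicate share object layouts across doses (a paired
design). This makes the ground-truth dose effect *exactly* monotone, which
is what the monotonicity invariants test. Ground-truth per-well area is the
pixel count of the union of the sharp disks at render resolution — the area
a perfect segmenter could recover, so overlap is counted once.

Not emulated: tumouroid swelling under cytotoxic stress, gel breakage,
bubbles, infections, single-cell debris, non-circular morphologies, uneven
illumination. Passing tests therefore demonstrate correctness of the
computation, not robustness to every real-world artefact; in particular
real screens need manual inspection for swelling, which this growth model
cannot represent.

## Best-focus projection

The focus score is the variance of the discrete Laplacian — parameter-free,
offset-invariant, and strictly larger for a sharp edge than for any
Gaussian-blurred copy. Projection is tile-wise (default 64 px): a single
global best plane would defocus objects at other depths. Output tiles are
hard copies from the winning plane (ties break to the lowest plane index),
so every output pixel originates from exactly one input plane and the
per-tile provenance map is auditable. Seam artefacts between tiles are
accepted; blending would invent intensities.

## Thresholding

The cutoff is anchored on the background population rather than derived
from a two-class split (Otsu): early in an experiment objects may cover
well under 1% of the field, where Otsu's criterion degenerates but a
background-anchored rule is unaffected. The background level is the
histogram mode (256 bins over the image range); the spread is the median
absolute deviation of pixels within ±25% *of the intensity range* around
the mode, scaled by 1.4826 (normal-consistency). The window is defined on
the range, not on the mode value, so that the whole rule is equivariant
under affine intensity rescaling a·I + b — the classification mask is then
provably invariant, which the property tests exercise.

Two numerical choices:

- **Spread floor.** The spread is floored at 0.5% of the intensity range.
  Without it a noiseless image has zero spread, the cutoff coincides with
  the mode, and every infinitesimally darkened pixel (defocus tails,
  anti-aliased edges) classifies as object. The floor keeps the cutoff
  strictly separated from the background level.
- **Known bias.** Any pixel darkened below the cutoff counts as object, so
  covered area is systematically *over*estimated — by roughly half an edge
  pixel per object radius (≈ 3% for 30 px objects, ~10–20% for 10–15 px
  objects with defocused neighbours). This is an accepted property of the
  method, visible in the tests, not corrected for.

Binarised regions are hole-filled (tumouroid lumens must not split a
particle), labelled with 8-connectivity, and filtered: components below
`min_area` (default the area of a 40 µm-diameter disk, ≈ 1257 µm², matching
the smallest seeded fraction) are debris; border-touching components are
removed only if `exclude_border` is set. Merged (overlapping) tumouroids
are deliberately *not* split by watershed — merging is a known limitation
of the assay and splitting heuristics would trade one bias for another.

## Morphometrics

Area = pixel count · pixel_size²; equivalent diameter = 2·√(area/π);
circularity = 4π·area/perimeter², clamped into [0, 1]. The perimeter uses
the Crofton 4-direction estimator. Plain pixel-edge counting overestimates
a disk's perimeter by ~27% (circularity ≈ 0.6 for a perfect disk); the
often-used weighted contour-step estimator fixes disks but collapses on
thin shapes (a 1×10 px line gets perimeter 8 and nonsense circularity ≈ 2).
The Crofton estimate converges to the true contour length with object size
(disk circularity 0.88 at r = 5 px rising monotonically to 0.995 at
r = 100 px) and keeps elongated debris below 0.5, which is what a shape
filter needs. A single-pixel component is assigned its square contour
(4 pixel sides) and circularity 1 by convention.

## Readouts and normalisation

`relative_total_area` divides each day's covered area by the well's first
imaged day (the anchor day, recorded in outputs); the anchor maps to
exactly 1 and the readout is invariant under any rescaling of a well's
areas — the property that removes well-to-well variation in seeding
density and makes samples comparable on one scale. A well whose anchor-day
area is zero cannot be normalised and is flagged and excluded with a
logged reason rather than propagating infinities. `total_area` (whole-well
covered area) and `mean_size` (per-object mean area) are kept as two
distinct readouts because the terms are easy to conflate. Replicates are
summarised as mean ± SEM (sample sd over √n; undefined for n = 1), with n
adjusted per cell when wells are missing. Readout redundancy is reported
as pairwise-complete Pearson correlations over (well, day) observations,
excluding count.

## Dose–response model

Responses (treated value / same-day vehicle mean, one point per replicate
well so the fit sees true scatter) are fitted with the five-parameter
log-logistic y(x) = c + (d − c)/(1 + exp(b(ln x − ln e)))^f. The vehicle is
only the denominator, never a fitted point (log 0). The upper asymptote d
is not pinned to 1: normalised responses can exceed control.

Fitting is bounded least squares (`scipy.optimize.least_squares`, TRF) on
(b, c, d, ln e, ln f), with residuals evaluated through `logaddexp` so
extreme slopes cannot overflow. Initialisation is deterministic: c, d from
the extreme per-dose mean responses, e from the dose nearest the midpoint
response, slope sign from a log-dose linear regression, f = 1, expanded by
a fixed 3×3 multiplicative grid over (b, f); the best of the nine starts
wins. There is no random restart, so fits are exactly reproducible.

**The e–f identifiability ridge.** With a 5-point ladder the asymmetry f
and the location e are jointly near-unidentifiable: at realistic noise the
estimated uncertainty of ln e exceeds 1 (a factor-of-e uncertainty), and
free fits wander along an (e, f) ridge. When the free fit leaves e
undetermined within a factor of exp(0.5) (estimated standard error of
ln e > 0.5), the model refits with f fixed at 1 and flags the result
(`ill_conditioned`). Exact or near-exact data has near-zero standard
errors and keeps the full asymmetric fit. With fewer than 5 distinct
concentrations, f is always fixed to 1 and flagged (`fallback_f1`).
Note the f = 1 family is symmetric under (b, c, d) → (−b, d, c); the
deterministic slope-sign initialisation selects the representation whose
b-sign matches the data's direction.

ED50 is the dose at the midpoint of the *fitted* span (c + d)/2, closed
form e·(2^{1/f} − 1)^{1/b}, undefined (flagged) when |d − c| is below
tolerance; defining the span from the observed extremes instead is a
configurable alternative reading, not the default. GI50 inverts the model
at the absolute response 0.5 and is undefined — flagged, not an error —
when 0.5 lies outside the fitted asymptote interval. Rankings report all
three criteria (1 − c descending, ED50 and GI50 ascending, undefined
last) side by side, because the criteria can genuinely disagree: a sample
can reach deeper maximal inhibition while another has the lower midpoint
dose.

Fits are produced per sample, day and readout (days configurable), since
dose–response structure emerges at different times in different samples.

## Problem sizes in tests

The test suite exercises the full pipeline on reduced scenes chosen to
keep geometry honest rather than large: 256–512 px wells, 3–5 planes, 4–8
objects, 2–4 replicates, and 3–4 imaging days; the 5PL recovery study uses
the full screen design (5-dose ladder × 4 replicates) over 100 seeds.
Recovery tolerances follow object scale: the 5% area-recovery bound is
asserted on well-separated 15–30 px objects, while scenes of 10–20 px
objects with defocused neighbours are allowed the method's documented
overestimation (up to ~25%).

## Known limitations

- Individual tumouroids are not tracked across timepoints; readouts are
  per-well aggregates.
- Merged objects stay merged; counts are biased down and mean size up as
  cultures grow dense.
- The covered-area overestimation bias means absolute areas should not be
  compared across very different object-size regimes; the relative
  (intra-well) readout is the robust one.
- The asymmetry parameter f of the 5PL is effectively not estimable from a
  5-point ladder at realistic noise; reported f ≠ 1 values are only
  meaningful for very clean data.
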