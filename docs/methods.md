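# Methods

## Model and assumptions

The classifier is purely radiometric and per-pixel. It rests on two
physical assumptions about nadir quadrat photographs of mixed grassland:

1. **Greenness separates living canopy.** Green leaves reflect more in the
   green band than in red and blue; senesced material, litter, soil crust
   and bare soil do not. After normalization this becomes the rule
   `(G − R) > g1 ∧ (G − B) > g2`.
2. **Height separates dead canopy from dead ground cover.** Standing dead
   matter is in the sunlit upper canopy while litter, crust and soil are
   shaded below it, so SDM is brighter *in all three bands* than the
   understory. With GV removed, this becomes
   `R > d·mean_R ∧ G > d·mean_G ∧ B > d·mean_B`.

No spatial information is used: there is no morphological cleanup, no
minimum object size, no texture. A pixel's class depends only on its own
normalized color and the image-wide band means. Consequences: cover is
exactly invariant under block replication (resolution), and anything that
violates the two assumptions (bright flowers, green moss, sunlit soil) is
misclassified pixel by pixel.

## Preprocessing choices

* Standardization is **per image, per band** — mean and standard deviation
  over all pixels of that one band of that one image. This is what makes
  one threshold set transferable across photographs taken under different
  light: any affine transform of a band's digital numbers (exposure gain,
  offset) cancels exactly, which the tests assert to 1e-6.
* The standard deviation uses the population formula (divide by N). After
  the min–max rescale the choice is mathematically irrelevant; it is fixed
  for determinism.
* Normalized values are **kept as floating point** on [0, 1023]. Threshold
  statistics over reference regions are non-integral, and the band
  differences the rules compare must not be quantized; rounding (half away
  from zero) happens only when exporting a normalized band as a 16-bit
  grayscale PNG. The rescale is computed as `1023·((v−min)/(max−min))` —
  dividing before multiplying — so the extremes map to exactly 0 and 1023.
* A constant band cannot be standardized; it raises a degenerate-band error
  naming the image and band rather than returning a silent zero image.
  Likewise a zero-pixel crop is an error, not 0 % cover.
* Crop rectangles are 0-based, top-left origin, width/height in pixels;
  band statistics are computed **after** cropping so the quadrat frame
  never contaminates the normalization.

## Classification conventions

* Both rules use **strict** inequalities; a pixel whose difference equals
  the threshold exactly is excluded (pinned by the worked example of a
  pixel with `G − R = 60` at `g1 = 60`).
* The band means of the SDM rule are computed over **all** pixels,
  including those already classified GV; GV pixels are excluded only from
  SDM candidacy. GV takes precedence over SDM.
* Default parameters: `g1 = g2 = 60` (normalized-DN difference units),
  `d = 1` (dimensionless multiplier). Practical ranges: `g1`, `g2` in
  roughly 30–70 (lower for high exposure, senescence, bluish leaves;
  `g1 > g2` when green moss must be excluded), `d` in 0.5–2 (below 1 for
  dense two-layer dead canopies, above 1 against bright litter or light
  soil). Batch runs warn — but never refuse — outside these ranges.

## Parameter-selection workflows

`explore_gv_thresholds` reports min/max/mean/std of the two band
differences over a user-supplied reference GV region; the minima are the
candidate `g1`, `g2`. The reference mask is deliberately an input (hand
drawn, or the synthetic generator's ground truth): the method is
semi-automated by design and no automatic threshold optimizer is provided.
`sweep_d` and `sweep_g` evaluate the classifier over parameter grids;
because both rules are threshold tests, covers are monotonically
non-increasing in `g1`, `g2` and `d`, which the sweeps expose and the test
suite asserts on random images.

## Spectral validation

NDVI uses reflectance at 800 and 670 nm, CAI at 2030, 2100 and 2210 nm;
named wavelengths are linearly interpolated between bracketing samples
(exact on the 1 nm grids field spectroradiometers deliver). CAI is paired
with SDM **plus** observed litter cover (NPV): litter carries the same
cellulose absorption signal as standing dead material, so SDM alone does
not track CAI. The regression is ordinary least squares of cover on index;
the slope p-value is a two-sided t-test with n − 2 degrees of freedom
(the regression itself is delegated to `scipy.stats.linregress` and is
cross-checked in the tests against a normal-equations solution).

## Synthetic scenes

`generate_quadrat` allocates pixel counts by largest remainder (so realized
fractions match the request exactly), scatters them by a seeded shuffle,
and draws colors from per-component palette means plus Gaussian noise
(default std 8 DN per channel), clipped to 0–255. Default composition is a
mid-season mixed-grass quadrat: gv 0.30, sdm 0.20, litter 0.15, crust 0.10,
soil 0.25.

The default palette — GV (60, 180, 60), SDM (210, 160, 150), litter
(140, 95, 75), crust (100, 100, 100), soil (150, 115, 60) — is calibrated
so that the default thresholds (60, 60, 1) separate all five classes
exactly in the noise-free case, which is what makes the defaults testable.
The construction is deliberate:

* the understory (litter, crust, soil) is darker than the dead canopy in
  every band, as shading dictates;
* litter holds the green-band minimum and soil ties GV for the blue-band
  minimum, so after min–max normalization each has a band at 0 and the
  strict `>`-mean test can never label them SDM, for *any* mixture of
  fractions;
* GV holds the green-band maximum, so SDM's normalized `G − R` is strongly
  negative and color noise cannot push dead pixels over the greenness
  thresholds;
* crust is a neutral gray lichen; a *green* moss crust is kept as the
  separate `green-moss` preset precisely because it defeats the GV rule.

Under the default noise (std 8) this palette recovers GV cover within ±2
points and SDM cover within ±5 points of ground truth in ≈98 % of random
scenes (fractions uniform 0–0.6, renormalized); noise-free recovery is
exact.

Scenario presets encode the documented hard cases, each deliberately
violating one assumption: `bluish` (GV blue channel shifted +86 DN, so the
normalized G − B contrast falls between 32 and 60 and only a lowered `g2`
captures the canopy), `dense-sdm` (60 % SDM in two strata, the lower dimmed
×0.80, recovered only at `d < 1`), `light-litter` and `light-soil` (bright
understory components that pass the SDM rule at `d = 1`), `white-flowers`
(a 5 % bright-blob component that no practical `d` removes) and
`green-moss` (crust with `G − R` between 40 and 60, admitted by a lowered
`g1`).

What the synthetic scenes do **not** emulate: spatial structure (leaves,
shadows, specular highlights), mixed pixels at component boundaries,
vignetting or exposure gradients within one photograph, and the continuous
color variation of real vegetation. Passing the recovery tests therefore
shows the pipeline's arithmetic and its separability logic are correct
under the stated color model — not that the default thresholds achieve any
particular accuracy on real photographs, where the constants must still be
chosen per campaign.

Synthetic spectra are linear mixtures of three fixed piecewise-linear
endmembers sampled at 1 nm (GV: ρ670 = 0.05, ρ800 = 0.50; NPV: bright with
a Gaussian cellulose trough at 2100 nm, depth 0.08, width 35 nm; soil:
NDVI exactly 0.1). All three are exactly *flat* across 2000–2300 nm —
the CAI shoulders sit asymmetrically around 2100 nm, so even a uniformly
sloped segment would leave a spurious CAI offset. Mixing noise is capped at
std 0.002 reflectance. These are caricatures for exercising index
arithmetic, monotonicity and the validation join, not radiative-transfer
spectra.

## Numerical and interface conventions

* Cover percentages in CSV output are fixed at 4 decimal places so
  re-running an identical batch byte-reproduces the file.
* Mask PNGs encode classes as values 0 (other), 1 (GV), 2 (SDM); the
  palette colors are cosmetic.
* Batch processing is order-deterministic (lexicographic filenames); a
  failing image is logged, skipped and counted, and never emits a partial
  row.
* All randomness (scenes, spectra, test images) flows through
  `numpy.random.default_rng` seeds; identical seeds byte-reproduce scenes.

## Problem sizes

Default synthetic scenes are 100 × 100 pixels (10⁴ pixels); recovery
statistics use 50 scenes, reference-equivalence checks 200 random images up
to 64 × 64, monotonicity suites 20 images × 10-point grids, and validation
closure 20 paired quadrats. Covers are resolution-invariant by
construction, so these sizes probe exactly the same arithmetic as
multi-megapixel field photographs.

## Known limitations

* Everything that is neither GV nor SDM is a single "other" class; litter,
  crust, soil and rock are not separated.
* White flowers cannot be excluded by any `d`; they must be handled at
  sampling time.
* A pooled-across-dataset variant of the SDM band means is not implemented;
  means are always per image.
* No white-balance, vignetting or lens-distortion correction; the
  standardization absorbs only affine illumination differences.
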