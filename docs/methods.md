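# Methods

## Measurement model

A field of view (FOV) is a single-channel grid of non-negative intensities
(ADU). The pipeline assumes condensates are compact bright objects much
larger than one pixel, sitting on a background whose variation is slow
compared with the droplet scale, with approximately Gaussian detector
noise. Three readouts are computed per FOV.

### Preprocessing

1. **Resize** (default factor 0.5, block mean). Droplets span many pixels,
   so halving resolution loses no feature information while quartering the
   cost of everything downstream. Block averaging preserves the global mean
   intensity, which the granulometry scaling depends on. Non-integer
   factors fall back to anti-aliased resampling.
2. **Rolling-ball background subtraction.** The background estimate is the
   morphological opening of the image by a ball-shaped structuring element
   of radius `ball_radius_px` (default 2× the largest schedule diameter, so
   the ball can never descend into a droplet). For radii above 16 px the
   estimate is computed on a block-averaged copy and re-expanded by
   bilinear interpolation — the standard large-radius speedup, accurate
   because the background is smooth by assumption; the interpolated
   estimate is additionally clamped below the local signal so subtraction
   can never produce negative values.

### Granulometry by successive area opening

The sieving schedule is a uniform diameter grid `x` from `x_min` to `x_max`
step `dx` (defaults 2–50 px step 2; screen configurations in this
repository use 2–24 px on the resized image, matched to ~6 px resized
droplets). Each diameter maps to a pixel-area threshold. The default
formula is `a_i = 2π(x_i/2)²` — twice the area of a circle of diameter
`x_i`. A geometric circle area `π(x_i/2)²` is available via
`area_formula="circle"`; both are legitimate diameter→area calibrations,
and the choice only relabels the x-axis of the spectrum (by a factor √2 in
effective diameter), leaving normalisation, moments and all downstream
comparisons structurally unchanged. The factor-of-two variant is the
default because it is the stated calibration of the procedure this
implements; the discrepancy between it and a literal circle area is
documented here rather than silently resolved.

Openings are applied successively: because area openings are absorbing
(`open_a ∘ open_b = open_max(a,b)`), opening the previous result at the
next threshold equals opening the original, at a fraction of the cost. The
per-bin loss `L_i = Σ(O_{i−1} − O_i)` makes bins disjoint and telescoping:
cumulative loss is non-decreasing and totals input-minus-final-opening
intensity exactly (asserted by tests). `y_i = L_i / mean(input)` makes
spectra comparable across FOVs of different brightness; the divisor is
recorded in the result for auditability. Division (not multiplication) is
used so that uniformly brighter images do not report proportionally larger
spectra. Stopping at `x_max` truncates the spectrum; the residual intensity
is retained on the result object.

Normalisation rescales `y` so `Σ y Δx = 1` (enforced to 1e-9 by the data
type; achieved to machine precision). An all-zero image produces an
all-zero, `empty`-flagged spectrum, and normalisation of zero mass raises —
empties fail loudly rather than silently contributing degenerate moments.

Moments are the literal discrete Riemann sums of the normalised spectrum
(non-excess kurtosis: a Gaussian-shaped spectrum gives ≈ 3; verified to 1%
against direct summation on a discretised Gaussian). When `σ² = 0` (point
mass) the standardised moments are undefined and reported as absent rather
than infinite. `σ³`, `σ⁴` derive from the same `σ² ` with `σ = +√σ²`.

Connectivity is 8-connected throughout (classical 2-D granulometry
default), configurable.

### Segmentation

Global threshold → 8-connected components → discard components below
`min_area_px2` (default 4 px², hot-pixel rejection) → per-droplet geometry
and intensity. Circularity is `4π·area/perimeter²` with the weighted
perimeter estimator, clipped at 1 to absorb discretisation overshoot. The
default per-image Otsu threshold is replaced in screen mode by a single
plate-wide threshold pooled from the control FOVs: per-image Otsu
mis-thresholds wells where a compound has removed the droplets (it then
bisects the noise), which would inflate dissolution counts; a pooled
threshold keeps the droplet/background split constant across the plate.
The same pooling is applied across a titration series, where sub-threshold
concentrations give droplet-free fields.

### Wells, controls, classification

Per-well features are medians across the (default 5) FOVs — robust to a
single bad field; features undefined in some FOVs (mean diameter of an
empty field) are excluded from the median. A well fails QC when more than
half its FOVs have zero dynamic range; QC failures are withheld from
calling and listed in the report.

Control statistics are per-feature mean and sample sd (n−1) over the DMSO
wells, with the sd floored at `1e-6·|mean|` (absolute floor 1e-12) to avoid
zero division on degenerate plates. Calls use z-scores at `z_cut`
(default 3):

* **dissolution** — condensed-fraction z ≤ −z_cut, or droplet count *and*
  total droplet intensity both ≤ −z_cut;
* **enhancement** — condensed-fraction z ≥ +z_cut, or mean diameter *and*
  total intensity both ≥ +z_cut;
* **other** — otherwise, mean-circularity z ≤ −z_cut (elongation /
  aggregation phenotypes);
* **no_effect** — otherwise.

Precedence is dissolution > enhancement > other: a compound that empties
wells is a dissolver even if shape also shifts. The rationale string on
every call records which features fired. The exact rule set is an explicit
design choice — condensed fraction is the most direct single readout of
condensate integrity, with the paired count/intensity and diameter/intensity
rules catching effects that redistribute rather than remove signal — and
all thresholds are config-exposed and echoed in the report. Screen
percentages are rounded half-away-from-zero to integer percent.

### Titration tipping points

The saturation concentration is snapped to the tested grid: the smallest
concentration whose response metric (droplet count by default) reaches
`frac_of_max` (default 0.1) of the series maximum. Raising `frac_of_max`
can only move the estimate up-grid (monotonicity is tested). A series whose
metric never exceeds zero reports "not reached", and fold changes between
series are only defined when both tipping points were reached.

## The simulator

Synthetic FOVs contain flat-topped elliptical spots with a raised-cosine
rim of width 1.25 px reaching zero exactly at the nominal radius, on a
planar background plus clipped additive Gaussian noise. The flat-top/rim
profile was chosen over a profile tapering from the centre because it makes
the nominal diameter recoverable by thresholding (any threshold crosses the
spot within the ~1 px rim, so measured equivalent diameters sit within
~1.5 px of truth) while keeping the edge smooth and the analytic spot
integral exact; a centre-tapered profile would make every thresholded size
roughly half the nominal one and the ground truth unusable as such.
Droplet placement is rejection-sampled to non-overlap (1 px clearance) so
segmentation truth is unambiguous; overlap can be allowed by flag.
Elongation is area-preserving (semi-axes ×√ar and ÷√ar), so shape
perturbations change circularity without changing droplet area or carried
intensity — keeping the simulated "shape" phenotype orthogonal to
dissolution/enhancement, as a surface-tension phenotype should be.

Default study conditions: 384 wells × 5 FOVs, 64 DMSO control wells in the
outer column pairs, 320 compounds; ~12 droplets per FOV of ~12 px diameter
and 120 ADU peak on a 20 ADU background. The validation scenario uses
24 ADU noise (signal-to-noise 5, the low end of usable image quality),
5 FOVs per well, and 128×128 px FOVs — plate-shaped but desk-scale, sized
so a full recovery experiment (56 wells, 280 FOVs) completes in well under
a minute while every statistical ingredient of a full plate (control
spread, FOV medians, pooled thresholding) is present. Compound effects
rescale droplet count, diameter, peak intensity, or shift aspect ratio;
identity is `(1, 1, 1, 0)`. Titrations place
`round(n_max · logistic(s·(c/c_sat − 1)))` droplets at concentration `c`
(steepness `s` default 20, a sharp but finite transition; `s → ∞`
reproduces a step exactly).

What the simulator does **not** emulate: optics (no PSF convolution or
defocus, so droplet edges are sharper than real microscope data),
Poisson-dominated shot noise (additive Gaussian only by default),
overlapping or fusing droplets, multi-channel colocalisation, well-edge and
meniscus artifacts, and plate-position effects. Passing tests therefore
demonstrate the correctness of the measurement and calling machinery under
controlled conditions, not robustness to every real-world imaging artifact.

## Numerical choices and degenerate inputs

* Area thresholds are rounded **up** to whole pixels (a component must meet
  the full area to survive).
* Standardised moments switch to "undefined" below σ² = 1e-12 px².
* Circularity is clipped to (0, 1]; zero-perimeter regions (excluded by
  `min_area` in practice) would report 1.
* Condensed fraction is clipped to [0, 1] against rounding.
* Negative noise draws are clipped at 0 (detectors do not report negative
  counts); images are validated non-negative and finite on construction.
* Seeds: every stochastic object (field, plate, titration) carries its own
  seed; plates spawn per-well/per-FOV substreams so any FOV can be
  regenerated in isolation and generation is byte-reproducible.

## Known limitations

* Touching droplets are segmented as one object (no watershed splitting by
  default; the simulator's non-overlap default makes this moot in tests).
* The granulometry x-axis is a sieving scale, not a physical diameter: the
  area-threshold calibration (factor of 2 above) shifts it, and the
  spectrum mean for d px droplets sits at the first grid diameter whose
  threshold exceeds the droplet's pixel area, not at d itself.
* Per-image Otsu thresholding is unreliable on droplet-free fields; use
  pooled or fixed thresholds for screens and titrations (the defaults do).
* The classifier is a transparent, threshold-based stand-in for whatever
  combination of features and judgement a particular lab uses; its classes
  and cuts are config-exposed rather than claimed optimal.
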