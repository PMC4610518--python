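# Methods

## Measurement model

A pinhole camera clipped to the rim of a conically shaped glass images the
interior. The liquid surface is a horizontal circle whose radius follows
the wall profile `r(h)`; under the rim-mounted perspective the circle
projects to an ellipse, of which only the far-side arc — the line where
the liquid meets the wall away from the camera — is visible. Two
pixel-space quantities summarize a frame:

* `level_px` — the height of the horizontal line tangent to the top of the
  reconstructed ellipse, counted **from the bottom image edge**
  (`rows − y_top`). With this convention a fuller glass has a larger
  level, matching the calibration table; it is the one non-obvious sign
  convention in the package and is asserted throughout the tests.
* `area_px2` — `π · a · b` of the fitted ellipse.

Neither is a physical quantity: the fixed mirror offset used to complete
the arc (below) makes the fitted ellipse an instrumental observable whose
relation to millimetres is recovered empirically by the calibration maps.

## Pipeline stages and the choices in them

**Pre-blur and gradient mask.** Disk kernel of radius 3 px (normalized,
`scipy.ndimage.convolve`, nearest-edge padding); Sobel magnitude via
`skimage.filters.sobel`. The fixed threshold 0.005 is the documented
clean-frame setting; `auto` uses median + 2·MAD of the magnitude
distribution and is the right choice for noisy frames, where a fixed
threshold saturates. Mask cleanup dilates with a vertical then a
horizontal 3-px line element, fills enclosed holes, and erodes with the
same elements (border-touching regions are treated as filled).

**Vesselness.** `skimage.filters.frangi` (bright ridges, scales
{1, 2, 3} px), rescaled to [0, 1]. Automatic thresholding uses Otsu's
method: the response distribution is near-zero almost everywhere with an
order-one tail on tubes, and a median-based cut collapses to zero there.

**Curve scan.** The quadratic family `row = a·col² + b·col + c` with
a = 0.003, b in [−0.58, −0.14] in four evenly spaced steps (endpoints
included), and integer c over every row. Rasterization marks
`round(row)` per integer column with no anti-aliasing, so overlap is a
plain pixel count. Ties break toward the smallest c, then the smallest b.
The scan is exhaustive and is tested against a brute-force loop over every
(component, b, c) triple.

**Trace extraction.** Within the winning component, per-column vertical
runs taller than a cut are dropped. The cut defaults to 1.5× the median
column height of the component (minimum 3 px) rather than a fixed width:
the gradient mask of a thin bright curve is a band several pixels tall —
the edge responds on both sides of the ridge — so no absolute width
separates the band from attached clutter across blur settings, while
blobs are reliably much taller than the band's typical height. When a
column still holds several surviving runs, the run nearest the winning
scan curve is kept. Surviving pixels collapse to their vertical centroid,
pruned columns are bridged by linear interpolation, and the trace is
smoothed by a centered 5-px moving average.

**Mirror completion and fitting.** The trace is point-reflected through
its centroid (the only 180° rotation that makes the copy "the opposite
side" while preserving the column extent) and translated so its lowest
point sits 50 px above the bottom edge — the fixed-offset reconstruction
rule. Fitting solves the algebraic least-squares conic: `ls_conic`
constrains the six coefficients to unit norm (smallest singular vector)
and classifies the result, returning a typed "no ellipse" (`None`) for
parabolas/hyperbolas/degenerate input; `direct` applies the
ellipse-specific constraint 4AC − B² = 1 (Fitzgibbon, block-stabilized);
`taubin` solves the gradient-weighted generalized eigenproblem. Points are
centered before fitting for conditioning and the conic is un-centered
afterwards. All three agree to 1% on well-conditioned input and recover
exact samples to 1e-6; `skimage.measure.EllipseModel` serves as an
independent cross-check in the tests, never as the implementation.

**Validity gates.** Two checks convert silent failures into the typed
"unmeasurable frame" outcome that batch runs skip: (i) the extracted trace
must span at least 30% of the image width (the contact line crosses most
of the frame by geometry; narrow traces are specular blobs or rim
fragments); (ii) the RMS row distance between the fitted ellipse's upper
branch and the central third of the trace must be ≤ 3 px. On noise-free
synthetic sweeps the central deviation is bimodal — ≤ 1.6 px when the
reconstruction works, ≥ 5.7 px when the mirror completion degenerates —
and the gate sits in the gap. Low fills (≤ 15 mm) fail this gate
systematically: the arc sits so low that the mirrored copy overlaps it
and the fit no longer follows the arc. This mirrors the behavior of the
real system, whose three lowest-fill frames were exactly the ones excluded
or unmeasurable.

**Calibration.** The level map is ordinary least squares on the quadratic
basis (computed on centered x for conditioning and expanded back). The
area map `a·e^{bx} + c·e^{dx}` is nonlinear least squares
(`scipy.optimize.curve_fit`) with a deterministic multistart: slow-rate
seeds b₀ ∈ {±1e-6, ±1e-5}, decay seeds d₀ from a log-linear fit of the
gap below the plateau plus a fixed grid {−1e-3, −3e-4, −1e-4, −3e-5}, and
amplitudes (a₀, c₀) solved linearly at each (b₀, d₀); the converged start
with the lowest SS_res wins, so refits are bit-reproducible. Fit quality
is R² and the dof-corrected RMSE `sqrt(SS_res/(n − p))` (p = 3 and 4);
the identity `RMSE²·dof = (1 − R²)·SS_tot` is asserted in tests. The
printed form of the area map's slow rate is read as 2.51e-6 px⁻²: at any
plausible magnitude above ~1e-5 the model overflows over the observed
range, and the full-precision refit lands on 2.513e-6.

**Outlier screening.** Calibration rows are screened with externally
studentized deletion residuals on the level map: each candidate row is
scored by refitting the quadratic without it and standardizing its
prediction error by the refit RMSE and `sqrt(1 + h)` (h = prediction
leverage at the deleted point); the single worst row above k = 2.5 is
flagged per pass until none exceeds. Deleting before scoring keeps a
gross leverage point from hiding behind its own influence; peeling one
row at a time keeps it from dragging sound rows down with it; the RMSE
scale (rather than a replicate-tight MAD) tolerates the quadratic's mild
lack of fit at the range ends; and a 0.5 mm scale floor — roughly one
pixel through the level map — keeps near-interpolatory fits from flagging
quantization scatter. Screening uses the level map only: frames bad
enough to exclude corrupt the detected arc, and with it the level, grossly,
while the area measurement's legitimate replicate scatter (~10%) defeats a
pointwise rule. On the bundled table the rule isolates exactly the
published exclusions; rows with missing measurements are flagged from the
start; more than half the rows flagged raises.

**Volumes.** `V = (π/3)·h·(r₁² + r₂² + r₁r₂)/1000` mL. The bundled
table's reference volumes are reproduced by the convention h = the row's
own level, r₁ = the radius at the topmost calibrated level (32 mm),
r₂ = the row's radius — the only convention consistent with the printed
column; the literal between-levels convention (h = reference − row level)
is exposed alongside it. One printed entry (the 30-mm rows, 108 mL)
disagrees with every consistent convention by ~0.5 mL (the formula gives
107.45); the discrepancy is documented in the tests. Consumed volume
between two measured states uses h = |ℓ₁ − ℓ₂| with each state's
calibrated radius.

**Agreement.** Differences d = estimate − reference; bias = mean(d),
SD with ddof = 1, limits of agreement = bias ± 1.96·SD,
SE = SD/√n, and CV = 100·SD(d)/mean of paired means. The upstream
report of "SE 4.1 mL" is numerically closest to SD(d) (3.98 on the
bundled table); both are exposed.

## The synthetic scene generator

The generator renders what the pipeline assumes, not what a camera
captures. World frame: z up from the glass base; the wall radius
interpolates the measured profile of the calibration glass (36.5 mm at a
10 mm fill narrowing to 32 mm at 60 mm; height 60 mm; reference level
60 mm). The camera sits above the near rim point (mount height 15 mm),
looks into the glass at 40° below the horizontal, with a 110 px focal
length on a 160 x 120 frame. The liquid plane maps to the image by the
homography `H = K [r₁ r₂ R(p − C)]`, the circle's conic transforms as
`H⁻ᵀ Q H⁻¹`, and the recorded ground-truth ellipse is therefore exact,
not sampled. The visible arc is the upper (far-side) branch, drawn 2 px
wide at intensity 0.95 over a gentle radial vignette (0.34–0.42, chosen so
the background gradient stays below the documented edge threshold) with
two seeded specular blobs as clutter. Degradation adds Gaussian noise then
salt & pepper speckle (each hit pixel set to 0 or 1 with equal
probability), all via a single seeded generator; the degradation ladder
ramps both noises together (Gaussian variance 0.01 per 0.1 of speckle
density), so density 0 is the clean frame.

Camera declination, focal length and mount height are geometric
stand-ins chosen once so that the fill sweep 10–60 mm lands in frame with
tangent rows spanning ~86→24 px and arc curvature bracketing the scan
default; the real device's intrinsics are unknown. What the generator
does **not** emulate: refraction through the liquid, colored beverages,
wall reflections with structure (blobs are isotropic), lens distortion,
and illumination flicker. Passing tests therefore demonstrate the
pipeline's correctness on the geometry it assumes and its robustness to
speckle/Gaussian noise and isotropic clutter — not performance on real
glassware imagery.

Two properties of the real data emerge from the method rather than the
scene and are reproduced by the generator + pipeline combination: derived
level and derived area are inversely ordered (the fixed 50 px mirror
offset inflates the fitted ellipse as the arc approaches it), and the
lowest fills are unmeasurable.

## Noise-robustness study

`degradation_study` scores each filter at each ladder density by arc
recall: the fraction of true arc columns whose extracted trace row lies
within 2 px of the rendered arc, using the full detection path
(threshold → refine → scan → extract). This operationalizes "is the
feature still usable" — the upstream judgement was visual. On the bundled
scene the fixed-threshold Sobel route loses the arc at the first ladder
step (density 0.1) while the vesselness route still recovers it there
(recall ≈ 0.76); by density 0.2 the automated detector loses the arc
under either filter. The qualitative contrast — vesselness outlasts
Sobel — reproduces; the stronger claim that the feature stays visible
through density 0.5 is a statement about visual inspection of filter
output, not about automated detection, and does not reproduce here.

Under noise the practical operating point is the `auto` Sobel threshold,
which keeps single-frame level error under 1 px up to density ~0.3 on
clean-background scenes; the noisy end-to-end acceptance check scores a
drinking event (top reference → half glass) from the median of three
frames per state, the natural use of event-triggered capture.

## Problem sizes and runtime

All tests and the acceptance script run on synthetic 160 x 120 frames and
the 18-row calibration table. The end-to-end sweep uses 6 levels x 3
replicates; the brute-force scan oracle runs on ≤ 32 x 48 masks; the
parametric vertical-extent oracle samples 10⁶ boundary points. The full
suite runs in well under a minute on one CPU; the acceptance script in
seconds.

## Known limitations

* Single-glass calibration: the maps are specific to one glass/camera
  mounting; recalibration data is required for any other geometry.
* Fills at or below ~15 mm are unmeasurable by construction of the
  mirror-completion rule (as in the real system's excluded frames).
* The fixed mirror offset makes area a purely instrumental observable;
  the area map must absorb its nonlinearity, hence the exponential form.
* The published stdError of the level fit (1.49 mm) is not reproducible
  from the integer-printed calibration table (OLS gives 1.42 mm); the
  original fit presumably used unrounded pixel measurements.
* Oblique rotation equivariance of the discretized vesselness response
  holds only qualitatively for 2-px curves (the response drops ~15–20%
  from raster jagging); quarter-turn equivariance is exact away from the
  borders.
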