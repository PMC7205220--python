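# Methods

This note documents the measurement models, conventions and parameter
choices in `nodalmorph`, what the synthetic phantoms do and do not
emulate, and the package's known limitations.

## Coordinate and unit conventions

Pixel indices are row-major and 0-based; the physical position of a
pixel is `index × pixel_size_um` at the pixel center, with isotropic
pixels. All lengths are micrometers, ages are postmenstrual months,
percentages are on a 0–100 scale. Pixel size is mandatory input and is
never defaulted, because scan resolution varies between studies.
Surface curves are oriented so arc length increases cephalic → caudal
(in phantoms, increasing x).

## Surface geometry

The segmented epi/endocardial surface arrives as a one-pixel-wide
8-connected trace. Ordering it into a polyline is traversal-based: a
naive "no pixel with ≥3 neighbors" rule would reject legitimate
right-angle corners, because a corner forms an 8-connected 3-clique.
Instead the traversal walks from one endpoint preferring axial over
diagonal steps (a diagonal shortcut would skip the corner pixel) and
treats any ambiguous continuation, extra endpoint or unvisited
remainder as a topology error. Path length uses the standard digital
metric (1 per axial step, √2 per diagonal).

Each coordinate is then fitted as a cubic smoothing spline in a
chord-length parameter (`scipy.interpolate.UnivariateSpline`). The
smoothing parameter is the allowed mean squared residual per point in
µm²; 0 interpolates. The default is `pixel_size²` (1 px RMS): the
trace is quantized to the pixel grid, so demanding a closer fit only
chases grid noise, while much heavier smoothing would bias depth in
high-curvature regions. Because results can depend on this choice it is
an explicit config value (`smoothing_param_um2`), and the fit reports
its residual RMS — measured as point-to-curve distance, not distance at
equal parameter, so the value is not inflated by chord-parameter
distortion. Curves are evaluated densely (10 samples per input point),
carry cumulative chordal arc length, and are resampled at uniform arc
spacing (`floor(L/s)+1` samples); open surfaces are not extrapolated
beyond their endpoints.

## Depth

The distance map is the exact Euclidean distance transform on pixel
centers (`scipy.ndimage.distance_transform_edt`, no chamfer
approximation), scaled to µm. Depth along the surface is the node
distance map sampled at the fitted surface samples; these are sub-pixel
positions, so sampling is bilinear by default (nearest-pixel is a
config alternative). The spline may overshoot the pixel grid by a
fraction of a pixel at curve endpoints; samples are clipped within one
pixel of the grid and anything further out is an error.

The **nodal projection** assigns every node pixel to its nearest
surface sample (ties to the lower index, deterministically) and takes
the `[min, max]` interval of hit samples. The per-section minimal depth
is the minimum of the depth profile over this interval — depth directly
"above" the node — not over the whole surface; the whole-surface
minimum is computed alongside because published analyses do not always
state which was used.

Aligned depth topology places each AVN series on a common axis,
`offset = (section_index − origin_index) × section_interval`, with the
first transition-to-His section as origin. Origin identification is an
anatomical judgment and therefore metadata, never inferred.

Box statistics (per-section depth ranges) use the
exclusive-median-halves quartile convention: split the sorted sample at
the median, dropping the median element when n is odd, and take the
median of each half — for {100, 200, 300, 400, 1000}, Q1 = 150 and
Q3 = 700. Whiskers use the 1.5·IQR rule. The convention is fixed and
documented because quartile definitions differ between tools.

## Stain classification and coverage

Masson's trichrome renders myocardium red, collagen blue and
adipose/empty space white. Two pixel classifiers are provided:

* **dual red threshold** (default): red iff `R − B ≥ t_dominance`
  (rejects white and blue) **and** `R ≥ t_intensity` (rejects dark
  pixels). Defaults 50 and 120 on the 8-bit scale, both configurable;
  lowering `t_dominance` monotonically grows the mask. An alternative
  hue-window classifier (HSV) is available behind an explicit call for
  robustness on real stain variation.
* **white threshold**: white iff `min(R,G,B) ≥ t_bright` and
  `max − min ≤ t_spread` (near-achromatic brightness), defaults 200
  and 30.

Circular ROIs are centered at uniform arc positions on the fitted
surface — radius/spacing 150/75 µm (SAN) and 500/250 µm (AVN) — and
clipped at image borders. The per-ROI percentage is
`100 × class-positive / denominator` with denominator = ROI disc ∩
tissue ∩ *superficial set*; an empty denominator flags the ROI missing
(NaN), never 0.

"Superficial to the node" needs a pixel-level definition. The default
rule: pixel `p` is superficial iff its surface distance is strictly
smaller than the surface distance of the node pixel nearest to `p`
(computed via the EDT feature transform). This reproduces the intuitive
"between the node and the surface" region, excludes the node itself,
and degrades gracefully for oblique geometry. An alternative rule —
keep every non-node pixel shallower than the node's minimal depth — is
available (`superficial_rule: min_depth`) because the geometric rule in
the source methodology is underdetermined; sections without a node use
all pixels.

ROIs are labeled **cephalic / nodal / caudal** by comparing the
center's arc position with the nodal projection interval; the partition
is exhaustive and disjoint, and sections without a node label every ROI
`none`. Per-section summary percentages are unweighted means over a
region's valid ROIs.

## Statistics

Two response models in postmenstrual age: `y = a + b·age` and
`y = a + b·log(age)`, both ordinary least squares (statsmodels); the
log model is exactly the linear model on `ln(age)`. Natural log is the
default; a base-10 switch rescales `b` by `ln(10)` and changes nothing
else (`R²`, `F`, `P` are invariant). Model utility is tested against
the constant model: `F = ((SST − SSE)/1)/(SSE/(n−2))`, `P` from
`F(1, n−2)`. Degenerate cases are fixed conventions: constant response
(SST = 0) reports `b = 0, R² = 0, F = 0, P = 1`; a perfect fit
(SSE = 0) reports `P` at the double-precision floor with a
`perfect_fit` flag. Confidence intervals for `b` are the analytic
t-intervals from the OLS standard error.

Group comparisons use one-way ANOVA plus Tukey–Kramer post hoc tests:
`q = |mᵢ − mⱼ| / sqrt(MSE/2·(1/nᵢ + 1/nⱼ))` with adjusted `P` from the
studentized range distribution with k groups and N − k degrees of
freedom (scipy's quadrature, abs. tolerance ~1e-10; with two groups
this reduces to the pooled t-test). Adjusted `P` values are clamped to
the open interval (0, 1]: underflow reports the double floor.

Reported `P` values follow the convention `P>0.05` above 0.05,
`P<0.001` below 0.001, otherwise three decimals. Summaries are mean ±
sample SD (n−1); a single value reports its SD as absent, not 0.

Regressions default to per-heart scalars (per-heart minimum of section
minima, or per-heart mean coverage); a pooled per-section variant is
always computed alongside, because it is often unclear which unit of
observation a published fit used. Coverage fits report both the signed
rate and its magnitude, since decreasing trends are sometimes printed
as positive magnitudes.

## Synthetic phantoms

`nodalmorph.phantom` generates what the analysis assumes and nothing
more: a smooth single-valued surface (flat, sinusoidal or polynomial;
no overhangs), a disc — optionally an elongated ellipse, mimicking
compact-node cross-sections — at a controlled depth, three stain
classes with **exact** per-region volume fractions (largest-remainder
counting, randomly arranged), nominal class colors with Gaussian
per-channel jitter (default SD 8, chosen so the default thresholds
separate classes with >5σ headroom), serial stacks with a prescribed
per-section minimal-depth curve, and cohorts whose per-heart depths
follow the linear/log age model with additive Gaussian noise (the
regression-consistent default; no heteroscedasticity, since none is
specified for real data).

Depth ground truth is the distance from the *analytic* surface curve to
the node as actually generated (its rasterized pixel centers). This
agrees with the closed-form geometry to within half a pixel, is exactly
what an exhaustive pairwise oracle measures, and makes the generator's
contract testable: measured minimal depth must sit within
`pixel_size·√2` of truth on every phantom. Surface rasterization
requires slope ≤ 1 px/column so the trace is a single non-branching
8-connected curve; the default node center snaps to a pixel column so
the simple flat-surface examples have exact closed-form depths.

Phantoms deliberately do **not** emulate staining chemistry, sectioning
artifacts (tearing, folding — excluded sections are represented by
omission plus an exclusion log), uneven illumination, 3-D tissue
deformation, or gradual node-to-myocardium transitions. Passing tests
therefore demonstrate the correctness and calibration of the
*measurement chain*, not robustness to real-stain segmentation error.

## Demo study conditions

The demo pipeline simulates 8 hearts with ages geometrically spaced
over 4.4–58.3 months, sectioned every 100 µm at 4 µm/px. AVN stacks
(12 sections: extension/compact/transition/His regions in a 40/30/20/10
split) draw the per-heart minimal depth from
`−102.607 + 135.018·ln(age)` µm with 50 µm noise (clipped at 20 µm) and
a V-shaped per-section profile (60 µm/section) dipping at the last
compact section; the myocardial overlay fraction over the node follows
`(42.039 − 0.383·age)%` — the printed fit magnitudes with the
decreasing direction — with a richer cephalic and poorer caudal band.
SAN stacks (13 sections) use age-independent depths of 135 ± 116 µm and
a 43% white (adipose) fraction. These sizes keep the full demo, run
twice for the determinism check, around a minute on one core.

## Limitations

* Depths are 2-D in-plane distances; the true 3-D minimal distance
  across sections is not computed (no volumetric reconstruction).
* Node and surface segmentations and the anatomical region labels are
  inputs; the package performs no segmentation.
* The smoothing parameter of the published spline fits is generally
  unreported; results at high surface curvature depend on it, which is
  why it is exposed rather than hidden.
* Stain thresholds are calibrated for phantom palettes; real slides
  need per-study threshold tuning (or the hue classifier).
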