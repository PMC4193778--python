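# Methods

This note records the models implemented in `scallopsize`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real
survey imagery.

## Footprint and tilt geometry

The camera is treated as an ideal pinhole looking straight down at a
flat seabed. For a ground dimension D imaged from altitude h the view
half-angle is θ = arctan((D/2)/h); a tilt δ about the perpendicular
axis moves the two edge rays to θ+δ and θ−δ, so the imaged ground
dimension becomes D′ = h(tan(θ+δ) + tan(θ−δ)). D′ is even in δ and
never smaller than D; the symmetric form is identical to the
asymmetric-shift form h·tan(θ+δ) − h·tan(δ−θ). Pitch is assigned to
the along-track (image y) axis and roll to the across-track (image x)
axis, applied independently per axis. Angles are degrees at every
public interface and radians internally.

Tilt is reported as a **diagnostic** (the relative footprint inflation
(D′−D)/D) and not applied to individual shell measurements by default:
at the pitch/roll magnitudes of a trimmed survey vehicle (sd 1–2 deg)
the inflation is below 0.1% and far below the pixel-quantization error.
A flag on `measure_shells` applies the per-axis scale factors for
sensitivity analyses.

Assumptions: flat seabed within a frame, shells lying in the seabed
plane, altitude measured to that plane. Slopes, shell tilt and
altimeter bias are not modeled.

## Lens-distortion correction

The correction maps distorted pixel coordinates to physical
coordinates (cm) in the plane of a calibration checkerboard
photographed at altitude h_frame. Each output axis is an ordinary
least-squares fit on the full quadratic basis (1, x, y, x², y², x·y)
of the distorted pixel coordinates; the x·y interaction is included by
default (the superset choice — a pure second-order-terms variant is
available via `include_cross=False` for sensitivity checks). At least
6 correspondences in general position are required; rank-deficient
designs are rejected. Because the reference grid is in centimeters at
h_frame, distances between corrected points are physical lengths at
that altitude and the altitude ratio is the only remaining scale
factor in the measurement equation.

Pixel convention everywhere: origin at the top-left corner, x
rightward, y downward, 0-based. Corner detection is out of scope:
correspondences arrive as annotated point pairs.

A global polynomial is a deliberate choice over a physical
(Brown–Conrady radial) model: it requires no intrinsics, fits the
manual-digitization workflow, and its adequacy is measured directly by
the per-axis fit RMSE that the model object carries.

## Shell measurement and ground-truth correction

For a shell annotated at tip and base pixels, both points are mapped
through the correction, giving a span P in cm in the calibration
plane; the height estimate is S = P · h_photo/h_frame (similar
triangles). Exclusions before any distribution is built: shells
flagged dead (decolorized/whitish), shells partially outside the
frame, frames outside the altitude retention window, frames not drawn
in the per-transect random sample.

Defaults: altitude window [1.5, 2.5] m (images from higher up lack the
detail to identify and delimit shells), 25 frames sampled per transect
without replacement, both logged with per-transect retention
percentages so the filtering can be audited.

Endpoints are recorded to whole pixels, so each endpoint contributes
up to about one ground-sample distance (GSD ≈ 0.2 cm/px at 2 m for the
default sensor) of error, and annotators clicking inside the fuzzy
shell edge make the net effect a small systematic underestimation. The
correction is a simple linear regression of known on estimated heights
fitted on the category means of a ground-truthing experiment (planted
shells of measured height in categories 0.5 cm apart, default means
5.5/6.0/6.5/7.0 cm, 25 shells per category), then applied to every
individual estimate. Fitting on means rather than individuals mirrors
how such experiments are summarized; `calibration_mode="individuals"`
switches to a per-shell fit. The known-on-estimated direction is used
because the regression is subsequently used to *predict* true height
from an estimate.

## Nested random-effects analysis

Heights from repeated surveys are modeled as
y = μ + s_i + t_j(i) + f_k(ij) + ε with independent zero-mean Gaussian
random intercepts for survey, transect-in-survey and frame, plus
residual. Estimation is **maximum likelihood**, not REML, because the
survey effect is judged by a likelihood-ratio test between nested
models and ML log-likelihoods are the comparable quantities; REML
would be preferable for unbiased variance reporting and can be added
at the reporting layer if needed.

The log-likelihood is computed exactly in O(n) by collapsing the
hierarchy one level at a time: a group whose members have variances
v_i and common added variance τ contributes a closed-form "within"
term and is replaced by its precision-weighted mean with variance
1/Σ(1/v_i) + τ (a diagonal-plus-rank-one marginalization applied
recursively). This is algebraically identical to the dense
multivariate-normal density — the test suite verifies equality to
1e-8 against `scipy.stats.multivariate_normal` and against an R/lme4
ML fit — and handles arbitrarily unbalanced designs; no balanced-only
shortcut exists in the fitting path.

Numerical choices: optimization over log-variances (Nelder-Mead) with
μ profiled out as the generalized-least-squares mean; multi-start from
a method-of-moments estimate plus 4 jittered copies (simulation
studies in the tests use 2–3 starts to keep replicate counts high at
fixed runtime); convergence tolerance 1e-9 on the log-likelihood;
components below 1e-12 reported as exactly 0; a dataset with zero
height range short-circuits to the degenerate fit (μ = the common
value, all components 0). AIC = −2ℓ + 2k and BIC = −2ℓ + k·ln n with
k = 4 (no survey term) or 5 (full).

The survey LRT uses the χ²₁ reference by default, matching standard
mixed-model `anova()` output. The null value σ²ₛ = 0 lies on the
boundary of the parameter space, which makes this test conservative;
`boundary_mixture=True` applies the 50:50 chi-bar-square mixture. The
default reproduces the conventional table first; the better-calibrated
test is one flag away. The type-I-error simulation in the acceptance
suite uses a 5 surveys × 4 transects × 10 frames × 2 observations
design over 500 replicates — a size chosen so that the study estimates
the rejection rate tightly while the whole suite stays quick; the
variance-recovery study uses the full 5 × 4 × 25 × ~3 design over 50
replicates.

## Distributions and the gear comparison

Proportional distributions use half-open bins, default width 0.5 cm
over [2, 10] cm (configurable and always logged; real analyses should
set the range to their data). The repeated-survey confidence band is
the per-bin empirical quantile envelope across survey replicates
(linear interpolation); with only 5 replicates a quantile band is
honest about the information available, while `method="normal"` gives
the mean ± z·sd alternative. No two-sample test is offered between
AUV and dredge distributions: observations within frames and tows are
correlated, so nominal p-values from standard distribution tests would
be wrong. The comparison reports modal bins, binned means/medians,
supports and the overlap coefficient Σ min(p_a, p_b) = 1 − TV.

The dredge-selectivity filter (retain height ≥ ring diameter, default
6 cm) is a deliberate caricature used only in synthetic gear
contrasts; real dredge selectivity is a smooth curve and would need
gear-specific estimation.

## Synthetic-data generator

What it emulates: a downward pinhole camera (default 1024×768 px, FOV
53.1°×33.4°, so the footprint at 2 m altitude is ≈2.0×1.2 m and the
GSD ≈0.2 cm/px), quadratic forward lens distortion, per-frame
altitude (truncated Normal, mean 2.0 m, sd 0.35 m — so the [1.5, 2.5] m
window retains most but not all frames) and pitch/roll jitter (sd 1
and 2 deg), a Poisson shell field at 1 shell/m², a truncated bimodal
Gaussian size mixture (means 4.5/7.0 cm, sds 0.8/0.9, weights
0.35/0.65 — a long-lived, recruitment-limited population dominated by
large individuals), 15% dead shells, integer-pixel annotation
quantization, and the 5 surveys × 4 transects × 25-sampled-frames
hierarchy. Between-group variability enters as additive Gaussian
effects on log-height (multiplicative on height, keeping it positive;
at the small sigmas used this is indistinguishable from the additive
model the analysis fits). A separate generator
(`simulate_nested_heights`) draws directly from the additive nested
Gaussian model for estimator-calibration studies.

The forward distortion is constrained to the same 6-term quadratic
family as the correction. A true radial pincushion is a cubic map with
no exact quadratic representative, so `pincushion_strength` s builds a
quadratic caricature (cross-term corner bending, ~s of the half-sensor
extent at the corners). The fitted correction is then an approximation
of the map's true inverse — exactly the situation with a real lens —
and the inverse-approximation residual scales as s². At the default
s = 0.02 (a typical mild distortion) the residual is ≤ 0.04 cm over
the calibration grid, i.e. well below the quantization error.

What it does **not** emulate — and therefore what passing tests do not
show about real data: visibility/detection (every shell in frame is
annotated; no misses, no misidentified substrate), operator behavior
(no inner-edge clicking bias beyond rounding, single error-free
operator), optical effects (turbidity, vignetting, lighting), shell
orientation ambiguity (height vs diameter confusion), non-flat
seabeds, and altimeter error. Conclusions about estimator arithmetic,
bias-correction mechanics and test calibration transfer to real
surveys; conclusions about absolute accuracy do not.

All generators are reproducible bit for bit from their seeds; the CLI
threads a single config seed through every stage.

## Known limitations

- The quadratic correction extrapolates poorly outside the calibration
  grid's extent; grids should cover the sensor.
- The ground-truth correction assumes the bias seen on planted shells
  (good lighting, flat placement) transfers to survey conditions.
- Variance components at the boundary make standard-error-based
  inference on them unreliable; only the LRT is offered.
- The measurement chain treats every annotation as an independent
  shell; re-sighted shells in overlapping frames are not de-duplicated.
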