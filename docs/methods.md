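# Methods

This note documents the models, estimators and numerical choices behind
`vesselastica`, and what the synthetic data do and do not establish.

## Wall kinematics

The lumen boundary on frame i is a closed polygon; its circumferential
length L(i) is the polygon perimeter (sum of Euclidean edge lengths,
closing edge included). Circumferential strain is engineering strain
against a reference frame, ε(i) = (L(i) − L_ref)/L_ref. When a pressure
trace accompanies the contours the reference defaults to the
minimum-pressure (diastolic) frame, so strains are non-negative over the
cycle and the diastolic configuration is the natural zero; without
pressure, frame 0 is used. Strain is a ratio, so it is invariant under a
common rescaling of all frames, and for circular cross sections it equals
the radial (diameter) strain identically — both properties are exploited
as exact cross-checks against the phantom generator.

Two preprocessing steps decouple the length estimate from how the boundary
happened to be traced:

* **Uniform arc-length resampling** to a common vertex count (the maximum
  over frames, at least 128), so frames traced at different densities
  remain comparable.
* **Fourier-descriptor smoothing** (default 10 harmonics of the complex
  boundary signal x + iy). Independent vertex noise inflates a polygon's
  perimeter quadratically — each edge picks up √(a² + δ²) ≥ a — by an
  amount that fluctuates from frame to frame and leaks directly into the
  strain. Low-pass truncation suppresses it while leaving smooth lumen
  shapes essentially untouched; the operation is linear in the
  coordinates, so all the exact identities above survive. Shapes with
  genuine sharp features need the harmonic count raised or the smoothing
  disabled (`smooth_harmonics=None`), in which case
  plain resampled perimeters are used. `circumferential_length` itself
  never smooths; the exact polygon identities (unit square → 4, scaling
  homogeneity) hold verbatim.

Segmentation of B-mode-like frames casts rays from the intensity-weighted
lumen centroid (the lumen is dark) and takes, per ray, the sub-pixel
location of the maximum outward intensity gradient — the dark-to-bright
inner wall edge — with parabolic refinement around the discrete maximum.
A ray whose best gradient is below 5 % of the frame's dynamic range per
pixel counts as failed; a frame with ≥ 10 % failed rays raises a
segmentation error naming the frame, and isolated failures are filled by
periodic interpolation of neighbouring rays. This is deliberately a
geometric boundary tracker, not a speckle-tracking or RF-correlation
elastography method.

## Pressure–strain loop and elastic modulus

Pressure is the densely sampled catheter signal, strain the sparse
image-derived one, so the pressure is linearly interpolated onto the frame
times (never the reverse), restricted to the overlapping time window.
Multi-cycle acquisitions are pooled into one point cloud before fitting.

Two modulus estimators, selected by a recorded `method` field:

* **extrema** — E = (p_max − p_min)/(ε_max − ε_min), the classic pulse
  pressure over pulse strain form. Exact on noiseless linear loops, but it
  uses only four samples and inherits their noise.
* **loop-fit** (default) — a first-order viscoelastic regression. The
  strain is fitted as ε = a + b₁·p̃ + b₂·q, where p̃ is the centered
  pressure and q its time derivative rescaled to the pressure's standard
  deviation (the quadrature component). The reported modulus is the
  dynamic magnitude E = sign(b₁)/√(b₁² + b₂²), i.e. the
  pressure-to-strain amplitude ratio of the loop. Rationale: strain noise
  sits on the regressand, so ordinary least squares stays unbiased where
  any symmetric (principal-axis) fit is attenuated by the noise-inflated
  strain variance; and a pure phase lag between pressure and wall motion —
  which opens the loop into the hysteresis ellipse seen in real
  acquisitions — moves signal from b₁ into b₂ without changing the
  magnitude, so hysteresis does not bias E. On a noiseless zero-lag loop
  both estimators return the exact slope; both scale as E → cE under
  p → c·p and E → E/c under ε → c·ε. Known limitation: strong noise on
  the *pressure* channel would attenuate loop-fit (the regressors become
  noisy); with catheter-quality pressure this is negligible.

Measured on phantoms at 2 % radial contour noise across true moduli
{10, 50, 200} mmHg/strain and lags {0, 0.3} rad (20 seeds each), loop-fit
recovers E with per-condition median relative errors between 0.6 % and
4.2 %.

## Regeneration score

RS = (1 − |E_T − E_N| / |E_T0 − E_N0|) × 100 %, where (E_T, E_N) are the
graft and native moduli at follow-up and (E_T0, E_N0) immediately after
implantation. Absolute differences are the default so the score is
symmetric in over- vs under-stiffness; `signed=True` keeps raw differences
for sensitivity analyses. The score is left unclamped (a gap that grows
beyond baseline goes negative) because clamping would discard information
and the 0 %/100 % anchors are unaffected. Cohort aggregation uses each
animal's own month-0 records as its baseline, then reports mean ± SEM per
timepoint; because the score is a nonlinear function of the moduli,
averaging per-animal scores is *not* the same as scoring the group means —
the package tests document this explicitly, which is why group-level
modulus ratios and group-level scores are not mutually derivable.

## Scaffold degradation

Hydrolytic degradation is summarized by a single-exponential law
v(t) = v0·e^(−kt), fitted as a least-squares line on (t, ln v); half-life
is ln 2 / k (infinite for non-decaying fits). The fit always reports its
log-space RMSE because real series depart from first-order kinetics — the
packaged molecular-weight series visibly plateaus after week 13 (log-space
residuals up to ~0.8), and the module reports that misfit rather than
asserting fit quality. Biphasic or erosion-front models are out of scope.

Threshold readouts: `time_to_fraction` finds when the value first falls to
a fraction of v(0), by default by linear interpolation *in value space*
between the two bracketing measurements — the way a "half the strength is
gone between weeks 2 and 3" statement reads off a measured table — or from
the fitted rate (ln(1/f)/k); `first_time_below` reads the earliest
measured timepoint at or below an absolute threshold, with no
interpolation. On the packaged strength series these give 2.203 weeks to
half strength and week 9 for ≤ 0.1 N.

## Cohort statistics

The dispatcher formalizes the common two-stage protocol: an explicit
equality-of-variances screen (Levene by default, Bartlett available; α
configurable, default 0.05) selects Student's unpaired t-test (equal) or
the Mann–Whitney U (unequal) for two groups, and one-way ANOVA with
Dunnett many-to-one post-hoc comparisons against a named control (equal)
or Kruskal–Wallis (unequal) for three or more. Which screen outcome
produced which test is recorded in every result, and the routing can be
pinned (`route='anova-dunnett' | 'kruskal'`) when an analysis plan fixes
the test a priori. Dunnett p-values come from scipy's multivariate-t
formulation; its randomized quadrature is seeded (`random_state`, default
0) so identical inputs give identical results. Under equal-mean normal
simulations the two-group dispatcher's type-I error stays at the nominal
5 % level (verified over 2000 seeded replicates).

## Synthetic data: what it emulates, what it does not

The phantom implements the simplest generative model whose recovered slope
equals the planted modulus: sinusoidal pressure
p(t) = mean + A·sin(2πt/T), a linear (first-order compliance)
pressure-to-radius law r(t) = r0·(1 + (p(t−τ) − p_min)/E_true), hysteresis
as a pure phase delay τ (which yields the open, near-elliptical loops seen
in practice), circular cross sections with i.i.d. radial vertex noise, and
i.i.d. pressure noise. Defaults describe a caval-vein-like vessel: 4 mm
diastolic radius, 8 ± 2 mmHg pressure, 1 s cycle, 60 frames at 30 Hz (two
cycles), 64 contour vertices. Frame rate and acquisition length are
acquisition choices, not tissue properties; both are configurable, and the
pressure is sampled 10× per frame interval so frame times are an exact
subset of pressure times (as with a real catheter, pressure is the dense
signal). Peak strain relative to the diastolic radius is 2A/E_true, which
the generator echoes as ground truth.

Not emulated: realistic ultrasound RF/speckle physics (rasterized frames
use a signed-distance intensity profile with multiplicative Gaussian
speckle), non-circular or 3-D vessel geometry, respiratory motion,
catheter eccentricity, and nonlinear (strain-stiffening) wall behaviour.
Passing tests therefore establish the correctness of the *analysis chain*
under a known generative model — not that the chain is robust to every
artifact of in-vivo imaging.

The cohort generator draws moduli lognormally (moduli are positive): per
animal a level factor and a ratio-trajectory factor (both at
`between_animal_cv`, drawn once), then an independent factor per
measurement (`measurement_cv`). Defaults follow the published follow-up
design — 7 animals at months {0, 1, 2.5, 6, 12, 24} with stiffness-ratio
means {7.3, 2.3, 1.1, 1.0, 1.4, 1.1} — with 10 % between-animal and 5 %
measurement variability as a realistic regime. A single pair of CVs cannot
reproduce arbitrary per-timepoint spreads; analyses that need the exact
published per-group dispersion draw groups directly from the reported
mean ± SEM summaries instead.

Every generator takes a mandatory seed and never touches global random
state; identical spec + seed gives byte-identical CSV output.

## Pipeline

Stages run in dependency order (phantom → kinematics → modulus; cohort →
RS → stats), exchange plain CSV/JSON, and finish with a manifest of
SHA-256 artifact hashes, the seed and the package version. The master seed
pins the phantom stage (seed) and cohort stage (seed + 1). A re-run in the
same directory reuses a stage's outputs only when the previous manifest
came from the same config and the files still match their recorded hashes.
Manifests exclude the output directory's location, so runs in different
directories with the same config are hash-identical.

## Problem sizes

Test and acceptance runs use the generator defaults (60-frame phantoms, 64
vertices, 7-animal cohorts) and modest grids (6 phantom conditions × 20
seeds; 2000 replicates for type-I calibration; 200 for estimator-variance
comparison), chosen as the smallest sizes at which the checked properties
are stable. Image-based tests use 96–128 px frames and ≤ 6-frame stacks.
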