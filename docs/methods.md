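# Methods

`leafbrdf` models how a leaf surface redistributes incident light and how
that behaviour relates to measurable leaf anatomy.  This note records the
model, the conventions, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Measurement geometry

The package targets goniometer-style instruments in which a fixed collimated
source illuminates a leaf held in a rotatable holder, and a collimation lens
travels along a detection ring covering zenith angles from −5° to 175°.
A right-handed Cartesian frame is used: the beam travels along +Y (so the
surface-to-source direction is `L = (0, −1, 0)`), Z points vertically down,
X completes the frame.  The leaf inclination is read off the holder scale,
whose perpendicular reference sits at 95° (`θ_leaf = 95° − reading`); the
leaf normal is `N = (sin θ, −cos θ, 0)`.  The viewing direction uses the
spherical form `V = (sin θv cos φv, −cos θv, sin θv sin φv)`, which is
unit-norm and coincides with `L` at `θv = 0`; a legacy `as_printed` variant
(middle component `−sin θv`, then normalized) is kept behind a flag for
comparison with older reductions, but it cannot represent `θv = 0`.  The
half-vector is `H = (L+V)/‖L+V‖`; `α = ∠(N, H)`; `θh = arccos(L·H)`, which
equals half the phase angle between `L` and `V` for every valid frame.
Angles are degrees at all I/O boundaries and radians internally.  Frames
with the source or the detector behind the leaf plane (`L·N ≤ 0` or
`N·V ≤ 0`) are excluded from fitting rather than clamped.

## Calibration

Reflectance is reduced strictly by ratio against a Lambertian reference
whiteboard measured under identical geometry:

    f_samp = Φ_sample / (π · Φ_reference)   [sr⁻¹]

The solid angle and incident flux cancel, so no absolute radiometry is
required; 1/π is the bidirectional reflectance of an ideal white Lambertian
surface.  Whiteboard health is checked by regressing reflected intensity on
cos(θv) — a well-aligned instrument yields R² ≳ 0.99.

## Surface model

The BRDF is a Cook-Torrance microfacet model,

    f = F(n, θh) · D(α, σ) · G(L, N, V, H) / (c · (L·N)(N·V)) + k/π,

with the exact unpolarized dielectric Fresnel factor `F` (no absorption
term: the cuticle is treated as non-absorbing), the Beckmann slope
distribution `D(α, σ) = exp(−(tan α/σ)²)/(σ² cos⁴ α)` implemented exactly in
this form (note: many rendering texts include an extra 1/π), and the
Torrance-Sparrow shadowing/masking minimum for `G`.  The specular
normalization constant `c` is typeset ambiguously in the source literature;
it is therefore an explicit `convention` tag — `as_printed` (2π², the
default), `pi`, or `four` — and fitted parameters are reported together with
the convention, since they rescale with it.  Parameters: σ ∈ [0, 1] is the
RMS microfacet slope, k ∈ [0, 1] the Lambertian weight, n ∈ [1, 5] the
effective refractive index.  With n = 1 the Fresnel factor vanishes and the
surface is exactly Lambertian with value k/π.

## Parameter estimation

Both fitters minimize the unweighted SSE over all usable geometries pooled
across the scan's incidence angles, independently per wavelength, surface
and canopy layer.  The standard initial point is (σ, k, n) = (0.5, 0.5, 3)
and the stability box is [0.01, 0.01, 1.1]–[0.99, 0.99, 5].

* **Bounded least squares** — scipy's trust-region-reflective solver with
  tight tolerances; deterministic, and essentially exact on noiseless
  forward data.
* **Adaptive grid search** — deterministic two-layer coordinate descent:
  cyclic sweeps of σ, k, n over a coarse 1e-2 grid inside the bounds until
  the relative SSE improvement falls below 1e-12 (at most 50 sweeps per
  phase), then repeated per-parameter sweeps of a fine 1e-4 grid spanning
  one coarse step around the incumbent.  Ties break toward the smaller
  parameter value.  Two refinements stabilize the descent: (a) the model is
  linear in k, so each k sweep also offers the exact conditional optimum of
  k as a candidate; (b) σ and n jointly set the specular amplitude and pure
  coordinate descent can block on their ridge, so whenever the cyclic
  sweeps converge, a joint (σ, n) grid sweep with k profiled out is run as
  an escape (σ at the current resolution around the incumbent, n over its
  full range).  The SSE trace is non-increasing by construction.

Goodness of fit is reported as R² = 1 − SSE/SStot (undefined, and reported
as missing, when the observations are constant) and RMSE.

**Identifiability.**  σ and k are recovered to ~0.01 under 5% flux noise on
the standard geometry grid.  n is the weak direction: it enters only through
the Fresnel amplitude, so when the lobe is broad (large σ) or faint, 5%
noise leaves a median |Δn| around 0.1 — an information limit of the data,
not a solver artifact.  In the degenerate Lambertian limit (n = 1) the BRDF
carries no angular information at all: any per-scan R² there compares a
constant prediction with pure noise and is meaningless; fit quality should
be judged on the pooled fitted-vs-observed regression across surfaces whose
reflectance actually varies.

## Image-based roughness

Roughness of a leaf surface is quantified from a cross-section micrograph
as ρ = l_inner / l_outer: the pixel-path length of the extracted surface
edge divided by the length of the same profile after 1-D Gaussian
smoothing.  Segmentation is deliberately minimal and reproducible: Otsu
threshold inside the region of interest, largest connected tissue
component, per-column extremal pixel (topmost for adaxial, bottommost for
abaxial).  Path length uses the 8-connected (octile) metric — 1 per axial
step, √2 per diagonal step, generalized to max+(√2−1)·min for float
profiles — which, like any chamfer metric, sits a few percent above the
Euclidean arc length for oblique slopes; since inner and outer lengths use
the same metric, the bias largely cancels in the ratio.  The smoothing
bandwidth defaults to 2% of the ROI width (the original tool leaves it
unspecified); a sinusoidal profile of period p then keeps the amplitude
fraction exp(−2π²s²/p²), which is how the analytic oracle for the synthetic
fixtures is computed.  Five replicates with randomized ROI widths (30–80%
of the image) and positions reduce placement bias; everything is seeded.
Leaf tips and main veins are avoided by ROI choice, not detected
automatically.

## Traits

Pigments follow the classical spectrophotometric equations (Chl.a =
12.72·A663 − 2.59·A645, Chl.b = 22.88·A645 − 4.67·A663, Car. =
(1000·A470 − 3.27·Chl.a − 104·Chl.b)/229), yielding extract concentrations;
conversion to mg·dm⁻² is available when the extract volume and disc area
are supplied, and is otherwise skipped — the predictor z-scores its inputs,
so the scale is immaterial there.  Negative pigment values are flagged,
never clamped.  SLW is dry mass over area (g·m⁻²).  The derived features
are total chlorophyll and the a/b ratio, giving nine predictors in all:
T, SLW, Chl.a, Chl.b, Car., Chl.a+b, Chl.a/Chl.b, ρ, λ.

## Trait-based prediction

One stacking ensemble per target parameter (σ, k, n): an 8:2 seeded split;
z-scoring fitted on the training split; recursive feature elimination to 5
of the 9 features ranked by a seeded random forest; per-base-learner
(SVR, random forest, gradient boosting) hyperparameter grid search
minimizing 10-fold CV MSE on the training split; and a stacking regressor
whose linear meta-learner is trained on out-of-fold base predictions — the
standard leakage-safe construction.  Default grids are small published
values (SVR C ∈ {0.1, 1, 10}, ε ∈ {0.01, 0.1}; forest size {100, 300},
min leaf {1, 3}; boosting depth {2, 3}, learning rate {0.05, 0.1}); they
are configuration, not tuned constants.  The held-out report carries MSE,
R², the split sizes, the winning hyperparameters and the base learners'
test MSEs.  Everything is bit-reproducible given the split and learner
seeds.

## Canopy photon tracing

The tracer is deliberately minimal: a bag of triangular leaf facets
(meters, Z up), each with (σ, k, n) and a Lambertian transmittance τ
(default 0.05 — no published value exists, so it is an explicit input).
Per hit, the photon reflects with probability R(θi) — the
directional-hemispherical reflectance of the facet's BRDF, precomputed per
unique optics row on a 19-angle table by Gauss-Legendre × midpoint product
quadrature (64×64 nodes) and clipped to [0, 1] with a warning if the raw
integral exceeds 1 — transmits with probability τ (cosine-weighted into the
far hemisphere), and is absorbed otherwise; R + τ ≤ 1 is enforced at mesh
load.  Reflected directions are exact draws from the BRDF lobe: with weight
k/R a cosine-weighted diffuse draw, otherwise Beckmann-about-mirror
sampling of the half-vector with a rejection test against the exact
specular lobe (the analytic acceptance bound 8πF/c follows from the
bisector identity L·H = V·H).  Photons enter at the domain top along the
source direction; nearest-triangle intersection is Möller-Trumbore,
vectorized over facets.  A facet's *scattered* PPFD counts only photons
with at least one prior surface interaction; direct-beam interception is
tallied separately.  One photon carries source_ppfd × domain_area /
n_photons of flux; facet PPFD is accumulated flux over facet area.  Russian
roulette is off; tracing stops at 20 bounces, and the photon ledger
(absorbed + exited + terminated = emitted) holds exactly on every run.
Layer summaries bin facets by centroid height into equal-thickness slabs
with area-weighted means and a facet histogram over intensity bins
(defaults 0–40, 40–80, 80–150, >150 µmol·m⁻²·s⁻¹).

## Synthetic study conditions

No public dataset accompanies the instrument, so seeded generators define
the study conditions end to end:

* **Goniometer scans** — forward model on the standard grid: incidences
  {0, π/6, π/4, 11π/36}, ring every 5° over −5°..175°, in-plane azimuth;
  fluxes reconstructed by inverting the calibration (reference flux 1) with
  multiplicative Gaussian noise on the sample flux only (the reference is
  treated as well-averaged); default noise sd 0.05.
* **Whiteboard scans** — intensities ∝ cos θv over 19 angles in [0°, 90°),
  multiplicative noise, default sd 0.01.
* **Section images** — a bright tissue band with a sinusoidal upper edge;
  the analytic roughness of the generating curve comes from quadrature of
  √(1+y′²).
* **Trait tables** — 270 rows by default (54 leaves × 5 representative
  wavelengths 468.36, 556.26, 673.46, 819.88, 877.97 nm), trait ranges at
  field-plausible magnitudes (thickness 0.1–0.4 mm, SLW 20–80 g·m⁻²,
  ρ 1.0–1.6), and planted effects with the observed correlation signs:
  σ rises with ρ, k rises with wavelength, n falls with thickness and SLW.
  Target noise is relative (default 15% of each signal's sd) and targets
  are clipped to their physical bounds.
* **Canopies** — randomly placed, tilted triangular leaves in equal
  horizontal layers of a bounded box, with per-layer optics assignable from
  the six canopy-simulation parameter sets (σ, k, n) ∈ {(0.3, 0.01, 1.0),
  (0.3, 0.35, 1.0), (1.0, 0.01, 1.0), (0.3, 0.01, 2.2), (1.0, 0.35, 2.2),
  (0.3, 0.35, 2.2)}.

What the fixtures do **not** emulate: spectrometer dark current and
wavelength-dependent noise spectra, microscope aberrations and staining
variability, vein/tip structures in sections, real trait covariance beyond
the planted effects, and the geometry of real crop canopies.  Passing the
synthetic benchmarks therefore demonstrates correctness of the algorithms
under the stated forward models, not field performance on real leaves.

## Problem sizes and runtime posture

The test suite and the reproduction script run on a single CPU: scans of
148 geometries (~104 usable), 20-replicate fit benchmarks, 270-row trait
tables, canopies of 100–200 facets with 2×10⁴–10⁵ photons, and 4×10⁴–10⁵
photons for the two-plate radiometric check.  These sizes make every
statistic reproducible in minutes while keeping Monte-Carlo standard errors
small enough for 3σ-style assertions.

## Known limitations

* n is weakly identified from noisy scans when the specular lobe is broad;
  reported n values deserve wider error bars than σ or k.
* Fitted parameters are convention-dependent (the specular normalization
  constant); comparisons across studies must match conventions.
* The roughness metric is in pixel units and depends mildly on the chamfer
  metric and smoothing bandwidth; it is a relative, not absolute, measure.
* The tracer is single-band with per-band parameters, has no sky model, no
  spectral coupling, and treats transmission as Lambertian with a free τ.
* The specular rejection sampler becomes slow for extremely narrow lobes
  (σ ≪ 0.1) at grazing incidence; it falls back to a diffuse draw if no
  sample is accepted within 1000 tries.
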