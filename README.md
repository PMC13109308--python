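# leafbrdf

Leaf optics for plant phenomics: reduce angular reflectance scans to
bidirectional reflectance, fit Cook-Torrance surface parameters per
wavelength, quantify leaf-surface roughness from cross-section micrographs,
predict the surface parameters from phenotypic traits with a stacking
ensemble, and trace photons through 3-D canopies with BRDF-governed
scattering.

## Who this is for

Canopy photosynthesis models need per-leaf optical parameters — how much
light a leaf scatters diffusely, how sharp its specular gloss is, and how
its surface index bends the lobe — but measuring full bidirectional
reflectance distribution functions (BRDFs) leaf by leaf is slow.  This
package implements the complete analysis chain around a goniometer-style
instrument (rotating leaf holder, detection ring from −5° to 175°) and a
trait-based shortcut: once the link between anatomy and optics is trained,
cheap traits (thickness, specific leaf weight, pigments, section roughness)
stand in for the optical measurement.

## The model

Bidirectional reflectance is calibrated against a Lambertian whiteboard
measured under identical geometry, `f_samp = Φ_samp/(π·Φ_ref)` (sr⁻¹), and
modelled as a Cook-Torrance microfacet BRDF:

    f = F(n, θh)·D(α, σ)·G(L, N, V, H) / (c·(L·N)(N·V)) + k/π

* `F` — exact unpolarized dielectric Fresnel factor of index `n ∈ [1, 5]`;
* `D(α, σ) = exp(−(tan α/σ)²)/(σ² cos⁴ α)` — Beckmann slope distribution,
  σ ∈ [0, 1] the RMS microfacet slope;
* `G` — Torrance-Sparrow shadowing/masking factor;
* `k/π` — Lambertian diffuse term, k ∈ [0, 1];
* `c` — explicit normalization convention (default `as_printed` = 2π²).

Parameters (σ, k, n) are estimated per wavelength by bounded least squares
and by a deterministic two-layer adaptive grid search (coarse 1e-2, fine
1e-4).  Leaf-surface roughness from micrographs is ρ = l_inner/l_outer, the
raw edge length over its Gaussian-smoothed length.  The trait→parameter
predictor is a stacking ensemble (SVR + random forest + gradient boosting,
linear meta-learner on out-of-fold predictions) over nine phenotypic
features reduced to five by recursive feature elimination.  The canopy
tracer converts the fitted BRDF into per-hit reflection probabilities and
samples exit directions from the exact lobe.  See `docs/methods.md` for the
full account.

## Worked example

Fit a noisy synthetic goniometer scan (`examples/fit_goniometer_scan.py`):

```
scan: 148 geometries, 104 usable (44 behind the leaf plane)
 least squares: sigma=0.3014 k=0.3537 n=2.1596  R2=0.9950 RMSE=0.00951
 adaptive grid: sigma=0.3014 k=0.3536 n=2.1598  R2=0.9950 RMSE=0.00951
truth         : sigma=0.3 k=0.35 n=2.2
```

The scan was generated from (σ, k, n) = (0.3, 0.35, 2.2) with 5% flux
noise.  Both fitters recover σ and k to the third decimal and agree with
each other; n lands within 0.05 of truth (it is the weakly identified
parameter under noise), and R² ≈ 0.995 says the model explains all but the
injected noise.  The other scripts in `examples/` exercise the whiteboard
cosine-law check, section-image roughness, trait-based prediction
(held-out R² = 0.968 for σ on the default synthetic trait table, with
surface roughness dominating the feature importances), and canopy photon
tracing (upper-layer scattered light rising from ~18 to ~146 µmol·m⁻²·s⁻¹
as k goes from 0.01 to 0.35).

There is also a thin CLI exposing each stage:

```bash
leafbrdf synth brdf-scan --seed 2 -o scan.csv
leafbrdf fit scan.csv --method lsq -o fits.json
leafbrdf demo -o demo-out        # end-to-end smoke run
```

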