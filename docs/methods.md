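# Methods

This note records the models, the numerical choices, and the limits of what
the synthetic experiments can show. Symbols: `μa`, `μs` absorption/scattering
coefficients (cm⁻¹), `μs' = μs(1−g)` reduced scattering, `g` anisotropy,
`n` refractive index, `θ` surface inclination against the illumination.

## Image model and corrections

The data model is a pushbroom cube `I(i, j, λ)` on a regular pixel grid
(row = scan direction, column = sensor line, 0-based), normalized per pixel as
`I = (R − D)/(W − D)` from raw, dark and white-standard frames. Negative
values (noise below dark level) are kept and handled by validity masks;
clipping would bias every downstream fit. Pixels where `W − D ≤ 0` at any
band are invalid from the start.

Two multiplicative artifacts are corrected, in fixed order:

1. **Height**: camera–surface distance is `d = d_work − z` (higher surface ⇒
   closer; the sign convention is used consistently by the simulator and the
   correction). A quadratic `P(d)` is fitted per band to white-standard
   intensities at ≥3 distances, and `I` is multiplied by
   `ε = P(d_work)/P(d)`. A band-averaged scalar mode exists for speed;
   per-band is the default since the falloff may be chromatic. Distances
   outside the calibrated range extrapolate but flag the pixel.
2. **Lambert**: division by `cos θ = n·l`. Pixels with `cos θ < 0.1`
   (θ ≳ 84°) are masked rather than amplified — beyond the validated
   60–70° regime, `1/cos θ` multiplies noise without bound. The threshold is
   configurable.

The Lambert step refuses to run on cubes lacking the height-corrected
provenance flag, enforcing the order; a `require_height_corrected=False`
escape hatch supports Lambert-only workflows.

## Surface reconstruction

Laser-line triangulation converts the line displacement `ΔY` on the
observation camera into height through
`ΔZ = L/(tan β + tan(α − arctan(ΔY/f)))`. The relation yields relative
heights along the scan; absolute anchoring is a calibration matter the
simulator sidesteps by generating `z` directly, and `triangulate_height`
documents its per-point interpretation. Non-positive denominators
(geometrically impossible returns) invalidate the point with a warning.

Laser-shadow holes are filled by the discrete harmonic extension: the 5-point
Laplacian is zeroed on hole pixels with Dirichlet data from valid neighbors,
solved sparsely and exactly (direct factorization; the residual is orders of
magnitude below the 1e-8-of-range contract). Filled values obey the discrete
maximum principle. Normals come from central differences (one-sided at
borders), oriented toward the camera; an optional Gaussian pre-smooth
(σ in pixels, default off) is available for noisy profilometry since the
gradient amplifies pixel-scale height noise. Illumination defaults to the
vertical optical axis `(0,0,1)`, matching the corrected geometry; any unit
vector is accepted.

## Forward radiative transfer

The slab solver discretizes radiance into `M = 20` conical fluxes. The
quadrature is Gauss–Radau on cosine `(0, 1]` including μ = 1, so collimated
normal incidence sits exactly on a node. For refractive-index-mismatched
boundaries the internal Fresnel reflectance has a derivative kink at the
critical cosine `μc = √(1 − 1/n²)`; one smooth rule across the kink stalls
convergence near 1e-2, so the scheme splits there — Gauss on `(0, μc)`,
Radau on `(μc, 1]` — which restores `|R(M=20) − R(M=40)| < 1e-4`. This is
standard adding–doubling practice; the cone count alone does not fix the
node family.

Azimuthally averaged Henyey–Greenstein redistribution matrices are evaluated
in closed form via complete elliptic integrals and column-renormalized so a
conservative layer conserves energy exactly. Layers are initialized at
optical thickness `τ0 = τ/2^k ≤ 1e-4` with the exact single-scattering
kernel, column-normalized so the scattered fraction per cone is exactly
`a(1 − e^{−Δτ/μ})`; the start-layer truncation contributes ≲2e-5 to R.
Doubling then squares the layer up to `τ` (≤ 40 steps; the inner loop is a
compiled Gauss–Jordan kernel). Boundary interfaces are diagonal Fresnel
operators in the internal-cone basis (reciprocity makes the internal-angle
bookkeeping energy-correct; total internal reflection gives r = 1).
Index steps between layers get an interface operator only when the indices
differ — the two skin layers share one dispersion curve, so none arises there.
Slabs with total `τ > 10³` drop the bottom boundary (semi-infinite shortcut;
a 1-cm dermis transmits nothing measurable). The reported reflectance excludes
the first-surface specular component, mimicking crossed-polarizer detection;
unscattered light returning collimated from the bottom of a thick slab is
negligible in every regime used here.

The independent cross-check is an MCML-style Monte Carlo photon simulator
(weighted packets, HG sampling, Fresnel refraction at every interface,
Russian roulette below 1e-4 weight) sharing only the problem definition with
the solver. Agreement over a 20-point Latin hypercube spanning
`μa ∈ [0.1, 1.1]`, `μs' ∈ [8, 40]` cm⁻¹, `g ∈ {0, 0.82}`, `n ∈ {1, 1.4}` is
within `max(0.003, 3·SE)` at 1e5 photons.

## Sample models

**Phantom** (one layer, 2 cm): the pigment is pre-diluted 1:2272 in the
silicone base; concentrations quote the diluted absorber. Masses for target
fractional concentrations follow `m_abs = 2 C_abs m_A/(1 − 2 C_abs)`,
`m_sc = 2 C_sc (m_A + m_abs)`, `m_B = m_A + m_abs − m_sc`, with an optional
+1 g cup-wall adjustment. Absorption is
`μa = C_AB μ_AB + C_abs μ_abs/0.13246`; the constant reconciles the dilution
used when the pigment curve was measured with the recipe dilution, and both
it and the pre-dilution ratio live in `data/phantom_config.json`, not in
code. `C_AB = 1 − C_abs` by default (a config switch also subtracts the
scatterer fraction). The refractive index is the Sellmeier form pivoted at
436.4 nm. Scattering comes from Lorenz–Mie theory summed over the microsphere
volume-fraction distribution: `μ_s,i = 3 φ_i Q_sca,i/(4 r_i)`,
`μs = C_sc Σ μ_s,i`, `g = Σ μ_s,i g_i / Σ μ_s,i`. The Mie series is the
canonical one (logarithmic-derivative downward recurrence, Wiscombe
truncation); a coated-sphere mode (user-supplied shell index, real indices)
exists for shelled particles.

**Skin** (100-μm epidermis over 1-cm dermis): epidermal absorption is the
melanin power law `6.6·10¹¹ λ⁻³·³³ cm⁻¹` scaled by the melanosome volume
fraction plus the 0.25 cm⁻¹ bloodless baseline; dermal absorption sums
hemoglobins (volume fractions against whole-blood curves), bilirubin and
cytochrome c oxidase (mM against per-mM curves) plus the same baseline — the
mixed units mirror the underlying compilations and are recorded per table.
Both layers share `μs' = a (λ/500)^{−b}` with `b = 1.27` fixed, `g = 0.82`,
and a Cauchy-type dispersion. Bilirubin is not a free parameter and defaults
to 0 mM (overridable): the model includes it for completeness, but it is not
among the six fitted quantities and no canonical value is established for it
here.

### Synthetic tables

No machine-readable versions of the referenced chromophore compilations or
of the measured phantom ingredient curves exist, so `data/` ships synthetic
stand-ins built by `scripts/make_tables.py`: Gaussian band models with the
correct peak positions (Hb 430/556 nm, HbO2 414/542/577 nm with isosbestic
crossings, bilirubin 460 nm, cytochrome Soret + 605 nm α-band) and
physiological whole-blood magnitudes; a flat pigment curve and a weak medium
curve calibrated so the recipe range `C_abs = 3.6–37%` spans
`μa ≈ 0.1–1.1 cm⁻¹`; and a bimodal lognormal sphere distribution (volume
mode at 7 μm plus a fines mode at 1.3 μm, radii 1–16 μm) whose effective
sphere index 1.65 is chosen so `C_sc = 1.6–6.5%` spans `μs' ≈ 8–40 cm⁻¹`.
These calibrations reproduce the documented property *ranges*; the spectral
fine structure is not that of the real materials, so absolute fitted values
on real data require real tables. Everything downstream is table-agnostic.

## Inversion

Spectra are resampled to 430–700 nm at 5-nm steps (the range is
configurable; the red limit is the conservative choice between the two
windows the instrument supports) and matched by unweighted least squares
(optional inverse-variance weighting exists behind a flag; none is the
default because no weighting scheme is canonical for this data). Box
constraints use a logistic transform inside Levenberg–Marquardt, keeping the
optimizer smooth while fits driven into a bound remain detectable via
`at_bound` flags (within 0.1% of the span). `R²` is computed against the
mean-spectrum null model. Non-finite residuals mark a fit failed instead of
raising. The iteration cap defaults to 200.

Initialization follows the multi-start recipe: the mean spectrum of a small
reference region (default 10×10 at the scene center, where the surface is
flat) is fitted from `n_starts` uniform draws inside the bounds; the best-R²
parameters seed all pixels. Every draw is screened by its forward residual
and only the best few receive full LM refinement — on one CPU this keeps
1000 starts affordable without changing which basin wins. Map fitting then
proceeds pixel-by-pixel with the previous pixel's solution as a warm start.
Cubes are block-binned (default 8 spatial / 6 spectral) before fitting.

Map metrics: radial mean ± SD profiles about a chosen center, and the
*maximum valid inclination angle* — the largest mean-annulus `θ` such that
every annulus closer in stays within 5% (configurable) of the central value
(the innermost annuli by default).

## Synthetic scenes

Geometries: hemisphere (default radius 15 mm, the phantom mold size), tilted
plane, and a finger-like cylinder. Truth parameters are uniform or supplied
as per-pixel maps (the VOT phases use three presets encoding the occlusion
physiology: melanin constant, deoxyhemoglobin up during occlusion,
oxyhemoglobin overshooting after release). Spectra come from the same
forward model the inversion uses; artifacts are applied in closed form
(× cos θ, × P(d)/P(d_work)), so the correction closure is exact by
construction and tests separate artifact inversion from model error. Noise
is multiplicative Gaussian on the cube and additive Gaussian on the height
map (the instrument's stated Z resolution, 0.05 mm, is the natural scale);
laser-shadow holes are punched at random interior pixels. The
interreflection option adds a fraction of the scene-mean spectrum in concave
regions — deliberately non-physical, present only so tests can confirm the
cosine correction does *not* remove additive contributions.

What passing tests show — and what they do not: the closure, ordering and
recovery results demonstrate that the correction and inversion machinery is
self-consistent and that the artifact model (pure multiplicative cosine and
distance terms) is inverted exactly. Real scenes add effects the generator
only caricatures (interreflection) or omits (speckle, polarization residue,
registration error, chromatic illumination drift), so field performance
bounds must come from real phantoms, not from these tests.

## Problem sizes and determinism

Desk-scale defaults used by the test suite and the acceptance script: scene
grids of order 24×24 (closure) and 6×34 radial strips binned ×2 (paired
branch ordering), 20-point Latin hypercube × 1e5 photons (solver validity),
50 noise replicates (recovery), 8–24 multistart draws. A full-image fit at
instrument resolution is minutes-per-megapixel and embarrassingly parallel
over pixels; nothing in the method depends on the reduced sizes. All
randomness flows from explicit seeds (scene, fit config, script `--seed`);
reports embed the seed and a configuration hash, and identical configurations
reproduce bit-identical maps.

Noisy-recovery reporting: with 1% multiplicative noise the per-replicate
scatter of weakly-constrained parameters (a 0.5 vol-% blood fraction, a
low-contrast absorber) exceeds 10% — that is the conditioning of the inverse
problem, not an implementation defect — so the recovery criterion is assessed
on the replicate-ensemble mean (unbiasedness at n = 50), which lands within
a few percent of truth for every parameter of both models.

## Known limitations

* Interreflection in concave regions is not corrected (and cannot be, by a
  multiplicative cosine model); it is simulated only to prove that negative.
* The quadrature's internal-angle boundary treatment ignores the angular
  remapping of diffuse light crossing an index step between unequal media;
  for the single air interface this is the standard approximation, and the
  two skin layers share one index.
* The coated-sphere Mie path requires real indices; no shell index is
  bundled because none is established for the reference microspheres.
* Spatial registration between cube and height map is assumed done (the
  generator emits co-registered grids); an affine registration step for real
  instruments is out of scope.
* Layer reciprocity holds to ~1e-3 relative (the exact-conservation
  renormalization of the start layer slightly breaks kernel symmetry); energy
  conservation is exact to 1e-11.
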