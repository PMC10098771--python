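# Methods

`roughspr` simulates angular-interrogation surface plasmon resonance (SPR)
protein-binding detection on nanometre-rough gold films, and quantifies how
roughness changes the sensor's performance statistics. This note records
the model, the numerical choices, and the limits of what the simulations
can show.

## Physical model

The sensor is a Kretschmann stack illuminated through the substrate with a
TM (p-polarized) plane wave at λ = 633 nm:

* BK7 glass substrate, n₀ = 1.52 (semi-infinite),
* gold film, n = 0.18 + 3.43i, nominal total thickness 50 nm,
* optional protein layer: BSA, n = 1.35 (80 mg/mL), default thickness
  d = 5 nm,
* water ambient, n_s = 1.33 (semi-infinite).

Roughness replaces the top part of the gold by a random relief: a uniform
base of thickness 50 − h nm plus a rough layer of depth h, so the nominal
gold budget is fixed while the relief redistributes it laterally. The
relief is one-dimensional (heights vary along x only); the y-axis is an
invariant extension, which is consistent with prism-based TM illumination
(the incident E-field has no y-component) but not with high-NA focused
illumination.

The time convention is e^(−iωt); absorbing media therefore carry a
positive imaginary refractive index, and upward propagation is e^(+ik_z z).
All reported reflectances are the specular (zeroth-order) reflected
efficiency R₀: with a 1 µm unit cell several non-specular orders propagate
in the glass, but an angular-interrogation detector collects the specular
beam only.

## Rough-surface generator

One realization on a 1 µm unit cell of 200 columns (5 nm lateral
resolution):

1. draw an i.i.d. fair binary sequence b ∈ {0, 1}²⁰⁰ (Bernoulli ½) and
   scale by the maximum roughness height h;
2. filter in the spatial-frequency domain with the Gaussian transfer
   function G(k) = exp(−k²·cl²/8), where k is the angular spatial
   frequency (rad/nm) and cl the correlation length; this gives the
   surface a Gaussian autocorrelation exp(−x²/cl²) with 1/e length cl;
3. take the real part, shift the minimum to zero and rescale the span to
   exactly h, so every surface is characterized by its maximum
   peak-to-valley height h.

`cl → ∞` passes only the DC term; the generator returns the flat
(uniform-sensor) surface in that limit instead of renormalizing numerical
noise. The ensemble RMS roughness is ≈ 0.2·h, consistent with the
RMS-to-height ratios of annealed gold films reported in the AFM
literature.

A `quantize=True` variant re-thresholds the filtered profile at its median
into the two levels {0, h} — a correlated telegraph surface with ~50%
metal fill and vertical sidewalls. This variant is closer to a "rectangular
contour" reading of the construction and to the fill-factor-0.5 square
grating used as the roughness analogue in the field-map analysis; it also
produces much larger sidewall area (hence protein increment) at small cl.
The continuous profile remains the default; see "Reproduction limits"
below for which published observables each variant does and does not
recover.

## Coating geometries

Three structures per surface:

* **bare** — metal/water only (the reference spectrum);
* **top_only** — analyte occupying [height(x), height(x) + d) in every
  column: the same protein amount as a flat sensor, isolating the
  localized-plasmon (LSPR) contribution;
* **conformal** — analyte in every non-metal cell within Euclidean
  distance d of the metal (morphological dilation by a disk of radius d on
  the 5 nm × slice grid, periodic in x, with the semi-infinite gold base
  included so flat regions are coated too): sidewalls bound protein, so
  the amount grows with roughness.

`protein_area_increment` reports the conformal-over-top-only analyte
cross-section increase in percent, counted on the same discretized grid
(cell-centre to cell-centre distances; an independent brute-force dilation
oracle in the test suite pins this convention). On the 5 nm lateral grid,
sidewall cells appear once local steps exceed the coating thickness, so
the increment is negligible for gentle surfaces and grows steeply for
h ≳ 10 nm at small cl.

## RCWA solver

The TM fields are expanded in M Fourier harmonics (symmetric orders
m ∈ [−(M−1)/2, (M−1)/2]). Per z-slice the second-order system

    u'' = k₀² F₁⁻¹ (K_x F₂ K_x − I) u,     E_x ↔ V = F₁ W Q,

is diagonalized, where K_x is the diagonal of normalized tangential
wavevectors and the Toeplitz operators are built from analytic Fourier
coefficients of the piecewise-constant permittivity (no quadrature error).
Two factorization rules are implemented:

* `"li"` (default): F₁ = ⟦1/ε⟧, F₂ = ⟦ε⟧⁻¹ — Li's factorization, the
  correct treatment of the discontinuous products (continuous D_x across
  vertical walls, continuous E_z), which converges to the true Maxwell
  solution;
* `"classic"`: F₁ = ⟦ε⟧⁻¹, F₂ = ⟦ε⟧⁻¹ — the original coupled-wave TM
  formulation used by legacy solvers. At finite truncation it behaves like
  a slice-wise arithmetic-mean effective medium and concentrates spurious
  Gibbs energy at material corners. It is retained because reference
  results computed with legacy codes are reproducible only under the same
  rule.

Layers are assembled with the Redheffer star (scattering-matrix)
recursion; modal amplitudes are referenced at their entry faces so every
propagation factor has modulus ≤ 1 and stacks of hundreds of 0.1-nm slices
remain stable. Consecutive identical slices are merged exactly before
solving. Uniform slices use analytic modes (no eigendecomposition), which
makes uniform-stack sweeps cheap at any M and exactly equal to the
transfer-matrix solution. Grazing modes with q = 0 (e.g. the specular
order exactly at the critical angle) are nudged to 10⁻¹² so admittance
matrices stay invertible.

An independent transfer-matrix Fresnel oracle (`fresnel_reference`,
H_y-referenced amplitudes, same conventions) provides the exact reference
for uniform stacks; the solver agrees with it to ~10⁻¹⁴ at every
truncation.

Internal fields are reconstructed from per-layer modal amplitudes obtained
by combining the partial scattering matrices below and above each layer
(stable, no transfer-matrix growth), and reported as |E_x|² + |E_z|² for a
unit-amplitude incident electric field.

## Performance statistics

From a water/protein spectrum pair:

* dip position n₀·sinθ_sp: global minimum beyond the critical angle,
  refined by a 3-point parabolic fit; dips shallower than 0.01
  (plateau − minimum) or sitting on the scan boundary are flagged
  undetectable ("no SPR") and propagate as undefined metrics, never as
  silent zeros;
* sensitivity S = 2π n₀ Δsinθ_sp / (λ d Δn_s) in rad/µm² (λ, d in µm;
  Δn_s = 0.02), sign preserved;
* FWHM: each curve is normalized by its plasmonic plateau peak (the
  reflectance maximum between the critical angle and the dip) and the 0.5
  crossings nearest the dip are interpolated; widths are converted to
  wave-vector units Δk = (2π/λ) n₀ Δsinθ and averaged over the pair.
  The plateau normalization is deliberate: normalizing by the whole-scan
  maximum is dominated by the trivial rise of metal reflectance towards
  grazing incidence and widens the uniform-sensor value by ~10%.
  `full_max` and `dip_referenced` levels are available as options;
* intensity contrast ΔI = R(θ_c) − R(θ_sp) averaged over the pair, with
  θ_c = asin(n_s/n₀);
* average dip reflectance I_sp;
* FoM₁ = S/FWHM (exact identity), and the shot-noise figure
  FoM₂ = S·ΔI/(FWHM·I_sp^¼). The fourth-root reading is adopted because
  it reproduces the published uniform-sensor value within input rounding,
  while a literal fourth power is off by orders of magnitude; the fourth
  power remains available as a config switch;
* enhancement ratios against the uniform sensor:
  ER_rough = P_conformal/P_uniform, ER_LSPR = P_top_only/P_uniform,
  ER_protein = ER_rough − ER_LSPR (held exactly by construction), with
  percentage attribution of each component;
* linear responsivity: least-squares slope and R² of dip shift versus
  deposited thickness 0–10 nm (11 points, 1 nm spacing). The slope is
  reported per nm of protein.

## Monte Carlo pipeline

A condition (h, cl) is simulated over `n_surfaces` seeded surfaces
(per-surface seed = base_seed + index; the same surfaces feed all three
coating geometries — a paired design that cancels surface-to-surface
variance out of the enhancement ratios). Metrics are computed per surface
and then averaged (undetectable surfaces are excluded and counted); the
ensemble-mean reflectance spectra are stored as well on the common coarse
grid. A condition is flagged "no SPR" when more than half of its surfaces
are undetectable.

Fidelity profiles:

* **paper** — 100 surfaces, M = 151, 0.1 nm slices, uniform 0.01° angular
  grid. This is the source configuration; it costs hours of CPU per
  condition.
* **desk** — 10 surfaces, M = 41, 0.5 nm slices, and a two-stage angular
  scan: 0.2° coarse over the full critical-angle-to-grazing range plus a
  0.02° refinement window (±0.5°) around the dip. SPR dips here are
  degrees wide, so the two-stage scan changes the uniform-baseline metrics
  by < 0.1% (grid-invariance is tested) while cutting desk-condition cost
  to ~20–30 s per surface on one core.

Problem sizes used by the shipped tests: the stochastic acceptance checks
run the three published operating points at desk fidelity (N = 10); the
sampling-property checks use deliberately coarse conditions (M = 5–11,
1–2 nm slices) where only distributional behavior matters.

## Reproduction limits (read before comparing to the published tables)

The uniform-sensor baseline is reproduced quantitatively (S = 124.4 vs
122.59; n₀sinθ_sp = 1.4405 vs 1.440; FWHM = 0.410 vs 0.41; ΔI = 0.897 vs
0.90; I_sp = 0.0071 vs 0.007; FoM₁ = 303.6 vs 299.00; FoM₂ = 937.6 vs
980.66), as are the solver-level invariants (oracle equality, energy
conservation, SPP dispersion, h → 0 degeneracy).

The published *rough-surface* ensemble values are a different matter. An
extensive cross-check (both surface constructions × both factorization
rules × M = 41 and 151) shows:

* the continuous (default) surfaces converge, as M grows, to a weak
  perturbation of the uniform sensor — physically sensible for gentle
  sub-wavelength relief — and cannot produce the published bare-dip shift
  of +0.04 in n₀sinθ from a 3 nm relief, nor mean S ≈ −380 at
  (h = 3, cl = 10), nor S ≈ +1600 at (h = 9, cl = 8);
* binary (quantized) surfaces reproduce the published *scale* of several
  observables — the point-b dip position (~1.49 vs 1.506), heavy dip
  damping, the protein-increment contours, and the square-grating
  analogy — but not the published sign structure either;
* the corner-field "hundredfold" enhancement of the square grating is
  reproduced (ratio ≈ 80 vs ≈ 140) only under the legacy `classic`
  factorization at the published truncation M = 151; under the convergent
  Li rule the corner hotspot ratio is ~2–8. Corner |E|² diverges at sharp
  metal edges, so any such maximum is a truncation/grid-defined quantity.

The ensemble tests therefore assert the published sign structure under the
prescribed desk conditions and are expected to fail where that structure
is unreachable; the failure messages state the computed values. Users
comparing against the published rough-surface tables should treat those
entries as code-specific rather than as converged Maxwell results.

## Numerical details and edge cases

* Branch choice: q = sqrt(ε − κ²) with Im(q) ≥ 0 (decay upward), Re(q) > 0
  tie-break for lossless propagating modes; validated by energy
  conservation on lossless gratings to 10⁻¹⁴ and passivity on lossy ones.
* Efficiencies: R_m = |r_m|²·Re(q_m)/q₀ in the substrate,
  T_m = |t_m|²·Re(q_m/ε_c)/(q₀/ε₀); evanescent orders carry exactly zero.
* Angle grids start exactly at the critical angle (needed for ΔI) and end
  just below 90° (the grazing normalization is singular at exactly 90°).
* Dip refinement degenerates gracefully: if the 3-point parabola is not
  convex the raw grid minimum is returned.
* Thick-metal limit: at 100 nm gold the dip sits within 0.005 of the
  two-interface SPP dispersion value Re[(ε_m ε_s/(ε_m+ε_s))^½]; beyond
  ~150 nm prism coupling is too weak to leave a local minimum at all.
* Reproducibility: identical configs give bit-identical surfaces and
  summaries; per-surface metrics can differ at the last ulp between
  surfaces of a degenerate (flat) ensemble, so "zero variance" is asserted
  at 10⁻⁹.

## Known limitations

* One-dimensional roughness only; no 2-D (x–y) relief, no measured AFM
  import, no non-Gaussian correlation models.
* Single-wavelength material constants; no dispersion models.
* TM polarization only (the Kretschmann geometry needs nothing else).
* The synthetic surfaces emulate the *statistics* of rough films
  (height bound, Gaussian correlation, ~0.2·h RMS), not grain boundaries,
  overhangs, porosity or adhesion-layer effects of real evaporated gold;
  passing ensemble tests demonstrates correctness of the simulation
  machinery, not fidelity of any particular film.
* Absolute near-field magnitudes at sharp corners are discretization-
  defined (see above); only field ratios at fixed numerical conditions are
  meaningful.
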