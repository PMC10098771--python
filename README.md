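# roughspr

Simulation framework for quantifying how nanometre-scale surface roughness
of a plasmonic gold film changes the performance of an angular-interrogation
surface plasmon resonance (SPR) biosensor for protein-binding detection.

SPR sensors read molecular binding as a shift of the reflectance dip of a
Kretschmann stack (glass/gold/water). Real gold films are rough at the
nanometre scale, and roughness both scatters the surface plasmon (widening
and weakening the dip) and adds binding area on the sidewalls of the
relief. `roughspr` separates these two effects by simulating, for each
random rough surface, a protein coating **with** sidewalls (conformal) and
**without** (top-only), and comparing both against the ideal smooth
sensor.

The package is aimed at optical-biosensing researchers who want a
reproducible, fully scripted pipeline: Gaussian random rough surface
synthesis → rigorous coupled-wave analysis (RCWA) of the TM reflectance →
sensor performance statistics → Monte Carlo ensemble aggregation.

## Model summary

Stack (λ = 633 nm, TM): BK7 substrate (n₀ = 1.52) / uniform gold
(50 − h nm, n = 0.18 + 3.43i) / rough gold layer of depth h / optional BSA
layer (n = 1.35, d = 5 nm) / water (n_s = 1.33). Rough surfaces are
Gaussian-filtered binary noise on a 1 µm cell of 200 columns,
characterized by maximum height h and correlation length cl
(autocorrelation e^(−x²/cl²)).

From the water/BSA spectrum pair of a structure:

* sensitivity  S = 2π n₀ Δsinθ_sp / (λ d Δn_s)   [rad/µm²]
* dip position n₀·sinθ_sp, dip reflectance I_sp
* FWHM of the normalized dip in wave-vector units [rad/µm]
* intensity contrast ΔI = R(θ_c) − R(θ_sp)
* FoM₁ = S/FWHM,  FoM₂ = S·ΔI/(FWHM·I_sp^¼)
* enhancement ratios vs the smooth sensor, split into the localized-
  plasmon part (top-only/uniform) and the added-protein part
  (conformal − top-only).

The RCWA engine is a scattering-matrix TM solver with Li's inverse-rule
factorization (a legacy all-Laurent rule is available as an option) and is
validated against an independent transfer-matrix oracle to 10⁻¹⁴ on
uniform stacks. See `docs/methods.md` for the full model, numerical
choices, and a frank account of which published rough-surface observables
are and are not reproducible.

## Worked example

The ideal smooth-sensor baseline:

```python
from roughspr.montecarlo_pipeline import uniform_baseline
print(uniform_baseline().to_json())
```

```json
{
  "S": 124.41255003450115,
  "n0_sin_theta_sp": 1.4404527077959506,
  "FWHM": 0.4097443773239606,
  "delta_I": 0.8967155740260505,
  "I_sp": 0.007108578854058578,
  "FoM1": 303.63455100235706,
  "FoM2": 937.6919880573871,
  "flags": {}
}
```

Reading: a 5 nm BSA layer shifts the dip by Δ(n₀sinθ) ≈ 1.24·10⁻³,
i.e. a sensitivity of 124.4 rad/µm²; the dip sits at n₀sinθ_sp = 1.4405
(θ_sp ≈ 71.3°), is 0.41 rad/µm wide at half depth, nearly extinguishes the
reflectance (I_sp ≈ 0.007), and the contrast between the critical angle
and the dip is 0.90. These match the ideal-sensor reference values
(122.59, 1.440, 0.41, 0.90, 0.007, 299, 981) to within a few percent.

A rough-surface ensemble condition:

```python
from roughspr.montecarlo_pipeline import MonteCarloConfig, run_condition
summary = run_condition(MonteCarloConfig.desk(h=9, cl=8, base_seed=0))
print(summary.mean["conformal"]["S"], summary.n_valid)
print(summary.enhancement["S"])   # roughness / LSPR / protein split
```

Command-line equivalents (driven by one YAML config; flags override
scalars):

```bash
roughspr baseline --profile desk --outdir runs/base
roughspr condition --h 9 --cl 8 --profile desk --outdir runs/d
roughspr sweep --config myrun.yaml
```

Every run writes its artifacts (CSV/JSON/HDF5) plus a manifest with the
config hash, seeds and file checksums.

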