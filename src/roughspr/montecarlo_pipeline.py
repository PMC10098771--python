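"""Monte Carlo ensembles of rough-surface SPR simulations.

One *condition* is a roughness pair ``(h, cl)``.  For each of ``n_surfaces``
seeded random surfaces the pipeline builds the bare, top-only-coated and
conformally coated stacks, sweeps the TM reflectance from the critical
angle towards grazing incidence, forms the water/protein spectrum pair per
coating model and computes its performance statistics.  Statistics are
averaged across the ensemble (metrics first, per surface, then averaged —
the ensemble-mean spectra are kept as well), and enhancement ratios are
taken against the ideal uniform-sensor baseline.

Surfaces are shared across the coating models within a condition (paired
design: the same seed stream feeds all models), and per-surface seeds are
``base_seed + index``, so any subset of the grid reruns bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structure_builder import (
    MaterialSet,
    RoughnessSpec,
    CoatingModel,
    generate_rough_profile,
    build_layer_stack,
    uniform_stack,
    protein_area_increment,
)
from .rcwa_engine import HarmonicBasis, angular_sweep, AngularSpectrum
from .spectral_metrics import (
    SpectrumPair,
    PerformanceReport,
    compute_performance,
    enhancement_ratios,
    EnhancementReport,
    linear_responsivity,
    find_dip,
)

__all__ = [
    "MonteCarloConfig",
    "MonteCarloSummary",
    "run_condition",
    "sweep_grid",
    "responsivity_scan",
    "uniform_baseline",
]

COATED_MODELS = ("top_only", "conformal")


@dataclass(frozen=True)
class MonteCarloConfig:
    """One ensemble condition and the numerical fidelity to run it at.

    The ``paper`` fidelity profile reproduces the source configuration
    (100 surfaces, 151 harmonics, 0.1 nm slices, 0.01° uniform grid) and is
    hours of CPU per condition; the ``desk`` profile (10 surfaces, 41
    harmonics, 0.5 nm slices, 0.2° coarse scan with a 0.02° dip-refinement
    window) reproduces the ensemble signs and orderings at workstation
    scale.
    """

    h: float = 3.0
    cl: float = 10.0
    n_surfaces: int = 100
    base_seed: int = 0
    models: tuple = COATED_MODELS
    n_harmonics: int = 151
    slice_thickness: float = 0.1
    d_analyte: float = 5.0
    delta_ns: float = 0.02
    wavelength: float = 633.0
    period: float = 1000.0
    n_columns: int = 200
    angle_step: float = 0.01
    refine_dip: bool = False
    refine_step: float = 0.01
    refine_halfwidth: float = 0.5
    invalid_fraction_no_spr: float = 0.5
    factorization: str = "li"
    quantize_surfaces: bool = False
    materials: MaterialSet = field(default_factory=MaterialSet)
    profile_name: str = "paper"

    def __post_init__(self) -> None:
        if self.n_surfaces < 1:
            raise ValueError("n_surfaces must be >= 1")
        unknown = set(self.models) - set(COATED_MODELS)
        if unknown:
            raise ValueError(f"unknown coating models: {sorted(unknown)}")

    @classmethod
    def paper(cls, h: float, cl: float, **overrides) -> "MonteCarloConfig":
        return cls(h=h, cl=cl, **overrides)

    @classmethod
    def desk(cls, h: float, cl: float, **overrides) -> "MonteCarloConfig":
        """Workstation-scale fidelity (reduced ensemble and basis)."""
        defaults = dict(
            n_surfaces=10,
            n_harmonics=41,
            slice_thickness=0.5,
            angle_step=0.2,
            refine_dip=True,
            refine_step=0.02,
            refine_halfwidth=0.5,
            profile_name="desk",
        )
        defaults.update(overrides)
        return cls(h=h, cl=cl, **defaults)

    def surface_seed(self, index: int) -> int:
        return self.base_seed + index

    def roughness_spec(self, index: int) -> RoughnessSpec:
        return RoughnessSpec(
            h=self.h,
            cl=self.cl,
            n_columns=self.n_columns,
            period=self.period,
            slice_thickness=self.slice_thickness,
            seed=self.surface_seed(index),
        )


@dataclass
class MonteCarloSummary:
    """Ensemble statistics of one (h, cl) condition."""

    config: MonteCarloConfig
    per_surface: dict  # model -> list[PerformanceReport]
    mean: dict  # model -> {metric: float | None}
    std: dict  # model -> {metric: float | None}
    n_valid: dict  # model -> int
    mean_spectra: dict  # model/"bare" -> AngularSpectrum on the coarse grid
    enhancement: EnhancementReport | None
    protein_increment_mean: float
    no_spr: bool

    def to_rows(self) -> list:
        rows = []
        for model in self.per_surface:
            for metric in PerformanceReport.FIELDS:
                rows.append(
                    {
                        "h_nm": self.config.h,
                        "cl_nm": self.config.cl,
                        "model": model,
                        "metric": metric,
                        "mean": self.mean[model][metric],
                        "sd": self.std[model][metric],
                        "n_valid": self.n_valid[model],
                    }
                )
        return rows


def uniform_baseline(
    config: MonteCarloConfig | None = None,
    angle_step: float = 0.01,
) -> PerformanceReport:
    """Performance of the ideal smooth 50-nm gold sensor.

    Uniform stacks excite no order coupling, so a single-harmonic basis is
    exact; the fine default grid keeps the refined dip positions converged.
    """
    config = config or MonteCarloConfig()
    mats = config.materials
    basis = HarmonicBasis(1)
    ref = angular_sweep(
        uniform_stack(mats, analyte_thickness=0.0, period=config.period),
        basis, config.wavelength, angle_step=angle_step,
    )
    bnd = angular_sweep(
        uniform_stack(mats, analyte_thickness=config.d_analyte,
                      period=config.period),
        basis, config.wavelength, angle_step=angle_step,
    )
    pair = SpectrumPair(ref, bnd, config.d_analyte, config.delta_ns, mats)
    return compute_performance(pair)


def _sweep(stack, config: MonteCarloConfig) -> AngularSpectrum:
    return angular_sweep(
        stack,
        HarmonicBasis(config.n_harmonics),
        config.wavelength,
        angle_step=config.angle_step,
        refine_dip=config.refine_dip,
        refine_step=config.refine_step,
        refine_halfwidth=config.refine_halfwidth,
        factorization=config.factorization,
    )


def _accumulate_mean_spectrum(acc, spectrum, grid_angles):
    R = np.interp(grid_angles, spectrum.angles_deg, spectrum.R0)
    return R if acc is None else acc + R


def run_condition(
    config: MonteCarloConfig,
    baseline: PerformanceReport | None = None,
) -> MonteCarloSummary:
    """Simulate one roughness condition over its seeded surface ensemble."""
    if baseline is None:
        baseline = uniform_baseline(config)
    mats = config.materials
    reports: dict = {m: [] for m in config.models}
    mean_R: dict = {m: None for m in ("bare", *config.models)}
    grid_angles = None
    increments = []
    for i in range(config.n_surfaces):
        profile = generate_rough_profile(
            config.roughness_spec(i), quantize=config.quantize_surfaces
        )
        bare = _sweep(
            build_layer_stack(profile, mats, CoatingModel("bare")), config
        )
        if grid_angles is None:
            # common coarse grid for ensemble-mean spectra
            grid_angles = np.arange(
                bare.angles_deg[0], bare.angles_deg[-1], config.angle_step
            )
        mean_R["bare"] = _accumulate_mean_spectrum(
            mean_R["bare"], bare, grid_angles
        )
        for model in config.models:
            coated = _sweep(
                build_layer_stack(
                    profile, mats, CoatingModel(model, config.d_analyte)
                ),
                config,
            )
            mean_R[model] = _accumulate_mean_spectrum(
                mean_R[model], coated, grid_angles
            )
            pair = SpectrumPair(
                bare, coated, config.d_analyte, config.delta_ns, mats
            )
            reports[model].append(compute_performance(pair))
        if config.h > 0:
            increments.append(
                protein_area_increment(profile, config.d_analyte)
            )
    mean: dict = {}
    std: dict = {}
    n_valid: dict = {}
    for model, reps in reports.items():
        mean[model] = {}
        std[model] = {}
        valid_count = 0
        for metric in PerformanceReport.FIELDS:
            vals = [
                getattr(r, metric)
                for r in reps
                if getattr(r, metric) is not None
            ]
            mean[model][metric] = float(np.mean(vals)) if vals else None
            std[model][metric] = (
                float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                if vals
                else None
            )
        valid_count = sum(1 for r in reps if r.S is not None)
        n_valid[model] = valid_count
    no_spr = all(
        n_valid[m] < config.n_surfaces * (1 - config.invalid_fraction_no_spr)
        for m in config.models
    )
    mean_spectra = {}
    if grid_angles is not None:
        n0 = mats.n_substrate
        for key, acc in mean_R.items():
            if acc is None:
                continue
            mean_spectra[key] = AngularSpectrum(
                angles_deg=grid_angles,
                n0_sin_theta=n0 * np.sin(np.radians(grid_angles)),
                R0=acc / config.n_surfaces,
                r0=np.zeros_like(acc, dtype=complex),
                metadata={
                    "ensemble_mean": True,
                    "h": config.h,
                    "cl": config.cl,
                    "model": key,
                },
            )
    enhancement = None
    if not no_spr and set(("top_only", "conformal")) <= set(config.models):
        mk = lambda m: PerformanceReport(  # noqa: E731
            **{f: mean[m][f] for f in PerformanceReport.FIELDS}
        )
        enhancement = enhancement_ratios(
            baseline, mk("top_only"), mk("conformal")
        )
    return MonteCarloSummary(
        config=config,
        per_surface=reports,
        mean=mean,
        std=std,
        n_valid=n_valid,
        mean_spectra=mean_spectra,
        enhancement=enhancement,
        protein_increment_mean=float(np.mean(increments)) if increments else 0.0,
        no_spr=no_spr,
    )


def sweep_grid(
    h_values,
    cl_values,
    template: MonteCarloConfig,
    baseline: PerformanceReport | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run a grid of (h, cl) conditions; returns a long table + summaries.

    The table carries one row per (condition, model, metric) with ensemble
    mean, standard deviation and valid count; undetectable ("no SPR")
    conditions keep their rows with NaN means.
    """
    h_values = list(h_values)
    cl_values = list(cl_values)
    if not h_values or not cl_values:
        raise ValueError("empty (h, cl) grid")
    if baseline is None:
        baseline = uniform_baseline(template)
    rows = []
    summaries = {}
    for h in h_values:
        for cl in cl_values:
            cond = replace(template, h=float(h), cl=float(cl))
            summary = run_condition(cond, baseline)
            summaries[(h, cl)] = summary
            rows.extend(summary.to_rows())
    return pd.DataFrame(rows), summaries


def responsivity_scan(
    config: MonteCarloConfig,
    thicknesses_nm=tuple(range(0, 11)),
    include_uniform: bool = True,
) -> dict:
    """Dip shift versus deposited protein thickness, per coating model.

    All thicknesses of a model share the same seeded surfaces so the scan
    isolates the coating response.  Returns per-model dicts with the
    thickness list, mean dip positions (sin theta_sp), least-squares slope
    per nm and R².
    """
    thicknesses = [float(t) for t in thicknesses_nm]
    if len(thicknesses) < 3:
        raise ValueError("need at least 3 thicknesses")
    mats = config.materials
    out = {}
    if include_uniform:
        basis = HarmonicBasis(1)
        positions = []
        for t in thicknesses:
            sp = angular_sweep(
                uniform_stack(mats, analyte_thickness=t, period=config.period),
                basis, config.wavelength, angle_step=0.01,
            )
            positions.append(find_dip(sp).n0_sin_theta_sp / mats.n_substrate)
        slope, r2 = linear_responsivity(thicknesses, positions)
        out["uniform"] = {
            "thicknesses_nm": thicknesses,
            "positions_sin": positions,
            "slope_per_nm": slope,
            "r_squared": r2,
        }
    if config.h > 0:
        for model in config.models:
            positions = []
            for t in thicknesses:
                dips = []
                for i in range(config.n_surfaces):
                    profile = generate_rough_profile(
                        config.roughness_spec(i),
                        quantize=config.quantize_surfaces,
                    )
                    coating = (
                        CoatingModel("bare")
                        if t == 0
                        else CoatingModel(model, t)
                    )
                    sp = _sweep(
                        build_layer_stack(profile, mats, coating), config
                    )
                    dip = find_dip(sp)
                    if dip.valid:
                        dips.append(dip.n0_sin_theta_sp / mats.n_substrate)
                positions.append(float(np.mean(dips)) if dips else np.nan)
            slope, r2 = linear_responsivity(thicknesses, positions)
            out[model] = {
                "thicknesses_nm": thicknesses,
                "positions_sin": positions,
                "slope_per_nm": slope,
                "r_squared": r2,
            }
    return out
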