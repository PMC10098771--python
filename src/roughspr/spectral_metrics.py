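"""Quantitative SPR performance parameters from angular reflectance spectra.

Implements the sensor metrics used throughout the study, computed from a
pair of spectra (water reference vs protein-bound):

* sensitivity ``S = 2 pi n0 d(sin theta_sp) / (lambda d_BSA dn_s)`` in
  rad/µm² (lambda and d in µm),
* dip position ``n0 sin theta_sp``,
* ``FWHM`` — average half-maximum width of the two normalized dips in
  wave-vector units (rad/µm, conventionally labelled rad·RIU/µm),
* intensity contrast ``dI = R(theta_c) - R(theta_sp)`` averaged over the
  pair,
* average dip reflectance ``I_sp``,
* figures of merit ``FoM1 = S/FWHM`` and the shot-noise-motivated
  ``FoM2 = S dI / (FWHM I_sp^(1/4))``,
* enhancement ratios of a rough sensor over the ideal uniform one,
  decomposed into the LSPR and added-protein contributions,
* linear responsivity (dip shift vs deposited protein thickness) and the
  phase-detection response.

Metrics whose defining feature is missing (no detectable dip, a dip flank
that never re-crosses the half level) are reported as ``None`` with an
explanatory flag rather than silently zeroed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .rcwa_engine import AngularSpectrum
from .structure_builder import MaterialSet

__all__ = [
    "SpectrumPair",
    "DipLocation",
    "PerformanceReport",
    "EnhancementReport",
    "PhaseResponse",
    "find_dip",
    "sensitivity",
    "fwhm",
    "intensity_contrast",
    "average_dip_intensity",
    "figures_of_merit",
    "compute_performance",
    "enhancement_ratios",
    "linear_responsivity",
    "phase_response",
]

#: Minimum dip depth (plateau minus minimum reflectance) below which the
#: plasmonic dip is considered undetectable ("no SPR").
DIP_DEPTH_THRESHOLD = 0.01


@dataclass(frozen=True)
class SpectrumPair:
    """Water-reference and protein-bound spectra of one structure."""

    reference: AngularSpectrum
    bound: AngularSpectrum
    d_analyte: float = 5.0
    delta_ns: float = 0.02
    materials: MaterialSet = field(default_factory=MaterialSet)

    def __post_init__(self) -> None:
        if self.delta_ns <= 0:
            raise ValueError("delta_ns must be > 0")
        if self.d_analyte <= 0:
            raise ValueError("d_analyte must be > 0")

    def reversed(self) -> "SpectrumPair":
        return SpectrumPair(
            self.bound, self.reference, self.d_analyte, self.delta_ns,
            self.materials,
        )


@dataclass(frozen=True)
class DipLocation:
    """Refined plasmonic-dip position and depth of one spectrum."""

    n0_sin_theta_sp: float
    I_sp: float
    valid: bool
    reason: str = ""


@dataclass
class PerformanceReport:
    """The per-structure performance statistics of one spectrum pair."""

    S: float | None
    n0_sin_theta_sp: float | None
    FWHM: float | None
    delta_I: float | None
    I_sp: float | None
    FoM1: float | None
    FoM2: float | None
    flags: dict = field(default_factory=dict)

    FIELDS = ("S", "n0_sin_theta_sp", "FWHM", "delta_I", "I_sp", "FoM1", "FoM2")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class EnhancementReport:
    """Rough-over-uniform enhancement ratios for S, FoM1 and FoM2.

    For each metric: the total roughness ratio (conformal/uniform), the
    LSPR-only ratio (top-only/uniform) and the added-protein contribution
    (their difference); percentages attribute each component to the total.
    """

    ratios: dict  # metric -> {roughness, LSPR, protein, pct_LSPR, pct_protein}

    def __getitem__(self, metric: str) -> dict:
        return self.ratios[metric]

    def to_json(self) -> str:
        return json.dumps(self.ratios, indent=2)


@dataclass
class PhaseResponse:
    """Unwrapped reflection phase across the dip of one spectrum."""

    n0_sin_theta: np.ndarray
    phase: np.ndarray
    excursion: float
    ambiguous: bool


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three (x, y) points (unequal spacing)."""
    coeffs = np.polyfit(x, y, 2)
    a, b, c = coeffs
    if a <= 0:
        return float(x[1]), float(y[1])
    xv = -b / (2 * a)
    yv = c - b**2 / (4 * a)
    return float(xv), float(yv)


def find_dip(
    spectrum: AngularSpectrum, min_depth: float = DIP_DEPTH_THRESHOLD
) -> DipLocation:
    """Locate the plasmonic dip with 3-point parabolic refinement.

    The dip is the global reflectance minimum of the scan; its position is
    refined on the ``n0 sin theta`` axis.  A dip is flagged invalid when it
    sits on the grid boundary or when its depth (scan maximum minus
    minimum) falls below ``min_depth`` — the undetectable "no SPR" regime.
    """
    R = np.asarray(spectrum.R0)
    x = np.asarray(spectrum.n0_sin_theta)
    i = int(np.argmin(R))
    if i == 0 or i == R.size - 1:
        return DipLocation(float(x[i]), float(R[i]), False, "boundary")
    depth = float(R.max() - R[i])
    xv, yv = _parabolic_vertex(x[i - 1 : i + 2], R[i - 1 : i + 2])
    valid = depth >= min_depth
    return DipLocation(xv, max(yv, 0.0), valid, "" if valid else "no_spr")


def sensitivity(pair: SpectrumPair) -> float | None:
    """Protein-binding sensitivity S in rad/µm² (signed)."""
    dip_ref = find_dip(pair.reference)
    dip_bnd = find_dip(pair.bound)
    if not (dip_ref.valid and dip_bnd.valid):
        return None
    lam_um = pair.reference.metadata.get("wavelength", 633.0) * 1e-3
    d_um = pair.d_analyte * 1e-3
    delta = dip_bnd.n0_sin_theta_sp - dip_ref.n0_sin_theta_sp
    return float(2.0 * np.pi * delta / (lam_um * d_um * pair.delta_ns))


def _half_crossings(
    x: np.ndarray, Rn: np.ndarray, i_dip: int, level: float = 0.5
) -> tuple[float | None, float | None]:
    """Half-level crossings nearest the dip on each side (linear interp)."""
    left = right = None
    for j in range(i_dip, 0, -1):
        if Rn[j - 1] >= level > Rn[j]:
            t = (level - Rn[j]) / (Rn[j - 1] - Rn[j])
            left = x[j] + t * (x[j - 1] - x[j])
            break
    for j in range(i_dip, x.size - 1):
        if Rn[j + 1] >= level > Rn[j]:
            t = (level - Rn[j]) / (Rn[j + 1] - Rn[j])
            right = x[j] + t * (x[j + 1] - x[j])
            break
    return left, right


def _single_fwhm(
    spectrum: AngularSpectrum,
    wavelength_um: float,
    normalization: str = "plateau",
) -> tuple[float | None, str]:
    """Half-maximum full width of one dip in wave-vector units (rad/µm).

    ``plateau`` (default) normalizes by the reflectance maximum between the
    scan start (critical angle) and the dip — the peak of the plasmonic
    plateau adjacent to the dip.  ``full_max`` uses the whole-window
    maximum, which for metals is dominated by the trivial rise of
    reflectance towards grazing incidence; ``dip_referenced`` takes the
    half level midway between curve maximum and minimum.
    """
    R = np.asarray(spectrum.R0, dtype=float)
    x = np.asarray(spectrum.n0_sin_theta)
    i_dip = int(np.argmin(R))
    if normalization == "plateau":
        Rn = R
        level = 0.5 * R[: i_dip + 1].max()
    elif normalization == "full_max":
        Rn = R / R.max()
        level = 0.5
    elif normalization == "dip_referenced":
        Rn = R
        level = 0.5 * (R.max() + R.min())
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    left, right = _half_crossings(x, Rn, i_dip, level)
    if left is None or right is None:
        side = "left" if left is None else "right"
        return None, f"no_{side}_crossing"
    width_k = 2.0 * np.pi / wavelength_um * (right - left)
    return float(width_k), ""


def fwhm(pair: SpectrumPair, normalization: str = "plateau") -> float | None:
    """Average full width at half maximum of the two dips (rad/µm).

    Each curve is normalized by its own maximum over the scan window and
    the crossings of the 0.5 level nearest the dip are located; undefined
    when a flank never re-crosses the half level.
    """
    lam_um = pair.reference.metadata.get("wavelength", 633.0) * 1e-3
    w_ref, flag_r = _single_fwhm(pair.reference, lam_um, normalization)
    w_bnd, flag_b = _single_fwhm(pair.bound, lam_um, normalization)
    if w_ref is None or w_bnd is None:
        return None
    return 0.5 * (w_ref + w_bnd)


def _reflectance_at_critical(spectrum: AngularSpectrum, materials: MaterialSet):
    x_c = materials.n_ambient  # n0 sin(theta_c) = n_ambient
    x = np.asarray(spectrum.n0_sin_theta)
    if x_c < x[0] - 1e-9 or x_c > x[-1]:
        raise ValueError("critical angle outside the scanned grid")
    return float(np.interp(x_c, x, spectrum.R0))


def intensity_contrast(pair: SpectrumPair) -> float | None:
    """Average contrast between critical-angle and dip reflectance."""
    out = []
    for spec in (pair.reference, pair.bound):
        dip = find_dip(spec)
        if not dip.valid:
            return None
        out.append(_reflectance_at_critical(spec, pair.materials) - dip.I_sp)
    return float(np.mean(out))


def average_dip_intensity(pair: SpectrumPair) -> float | None:
    """Mean reflectance at the two plasmonic dips."""
    dips = [find_dip(s) for s in (pair.reference, pair.bound)]
    if not all(d.valid for d in dips):
        return None
    return float(np.mean([d.I_sp for d in dips]))


def figures_of_merit(
    S: float | None,
    FWHM: float | None,
    delta_I: float | None,
    I_sp: float | None,
    exponent_mode: str = "fourth_root",
) -> tuple[float | None, float | None]:
    """FoM1 = S/FWHM and the shot-noise FoM2 (signs preserved).

    ``exponent_mode`` selects how the dip depth enters FoM2: the default
    fourth root ``I_sp^(1/4)``; ``fourth_power`` uses ``I_sp^4``.
    """
    if S is None or FWHM is None or FWHM == 0:
        return None, None
    fom1 = S / FWHM
    if delta_I is None or I_sp is None or I_sp <= 0:
        return float(fom1), None
    if exponent_mode == "fourth_root":
        denom = I_sp ** 0.25
    elif exponent_mode == "fourth_power":
        denom = I_sp ** 4
    else:
        raise ValueError(f"unknown exponent_mode {exponent_mode!r}")
    fom2 = S * delta_I / (FWHM * denom)
    return float(fom1), float(fom2)


def compute_performance(
    pair: SpectrumPair,
    normalization: str = "plateau",
    exponent_mode: str = "fourth_root",
    min_depth: float = DIP_DEPTH_THRESHOLD,
) -> PerformanceReport:
    """All performance statistics of one water/protein spectrum pair."""
    dip_ref = find_dip(pair.reference, min_depth)
    dip_bnd = find_dip(pair.bound, min_depth)
    flags: dict = {}
    if not dip_ref.valid:
        flags["reference_dip"] = dip_ref.reason
    if not dip_bnd.valid:
        flags["bound_dip"] = dip_bnd.reason
    if flags:
        pos = None
        if dip_ref.valid or dip_bnd.valid:
            pos = float(
                np.mean(
                    [
                        d.n0_sin_theta_sp
                        for d in (dip_ref, dip_bnd)
                        if d.valid
                    ]
                )
            )
        return PerformanceReport(None, pos, None, None, None, None, None, flags)
    S = sensitivity(pair)
    width = fwhm(pair, normalization)
    if width is None:
        flags["FWHM"] = "missing_half_crossing"
    dI = intensity_contrast(pair)
    I_sp = average_dip_intensity(pair)
    fom1, fom2 = figures_of_merit(S, width, dI, I_sp, exponent_mode)
    pos = 0.5 * (dip_ref.n0_sin_theta_sp + dip_bnd.n0_sin_theta_sp)
    return PerformanceReport(S, pos, width, dI, I_sp, fom1, fom2, flags)


def enhancement_ratios(
    report_uniform: PerformanceReport,
    report_nosidewall: PerformanceReport,
    report_sidewall: PerformanceReport,
) -> EnhancementReport:
    """Decompose rough-sensor enhancement into LSPR and protein parts.

    For metric P: ER_roughness = P_sidewall/P_uniform (total effect),
    ER_LSPR = P_nosidewall/P_uniform (wave effect alone) and
    ER_protein = ER_roughness - ER_LSPR (added binding density), with the
    percentage attribution of each component to the total.
    """
    ratios = {}
    for metric in ("S", "FoM1", "FoM2"):
        pu = getattr(report_uniform, metric)
        pn = getattr(report_nosidewall, metric)
        ps = getattr(report_sidewall, metric)
        if pu is None or pu == 0 or pn is None or ps is None:
            ratios[metric] = None
            continue
        er_rough = ps / pu
        er_lspr = pn / pu
        er_prot = er_rough - er_lspr
        pct_lspr = pct_prot = None
        if er_rough != 0:
            pct_lspr = 100.0 * er_lspr / er_rough
            pct_prot = 100.0 * er_prot / er_rough
        ratios[metric] = {
            "roughness": er_rough,
            "LSPR": er_lspr,
            "protein": er_prot,
            "pct_LSPR": pct_lspr,
            "pct_protein": pct_prot,
        }
    return EnhancementReport(ratios)


def linear_responsivity(
    thicknesses_nm, dip_positions_sin
) -> tuple[float, float]:
    """Least-squares slope and R² of dip shift versus protein thickness.

    ``dip_positions_sin`` are ``sin theta_sp`` values (not multiplied by
    n0); the slope is the responsivity d(sin theta_sp)/d(thickness) per nm.
    """
    t = np.asarray(thicknesses_nm, dtype=float)
    p = np.asarray(dip_positions_sin, dtype=float)
    if t.size < 3 or t.size != p.size:
        raise ValueError("need >= 3 matching (thickness, position) points")
    shift = p - p[0]
    fit = stats.linregress(t, shift)
    return float(fit.slope), float(fit.rvalue**2)


def phase_response(
    spectrum: AngularSpectrum, window_halfwidth_deg: float = 2.0
) -> PhaseResponse:
    """Unwrapped reflection phase and its excursion across the dip.

    The excursion is the peak-to-peak unwrapped phase within
    ``window_halfwidth_deg`` of the reflectance minimum.  Flagged ambiguous
    when |r0| nearly vanishes inside the window (phase unwrap unreliable).
    """
    phase = spectrum.phase0
    i_dip = int(np.argmin(spectrum.R0))
    mask = (
        np.abs(spectrum.angles_deg - spectrum.angles_deg[i_dip])
        <= window_halfwidth_deg
    )
    win = phase[mask]
    ambiguous = bool(np.min(np.abs(spectrum.r0[mask])) < 1e-3)
    return PhaseResponse(
        n0_sin_theta=spectrum.n0_sin_theta[mask],
        phase=win,
        excursion=float(win.max() - win.min()),
        ambiguous=ambiguous,
    )
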