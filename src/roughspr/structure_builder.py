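"""Gaussian random rough gold surfaces and their x-periodic layer stacks.

This module is the synthetic-structure generator of the package.  A rough
plasmonic surface is drawn as a binary 0/1 column sequence, low-pass
filtered in the spatial-frequency domain with a Gaussian transfer function
whose width is set by the correlation length ``cl``, and affinely rescaled
so the profile spans exactly the requested maximum roughness height ``h``.
The profile is then discretized into thin z-slices and combined with one of
three protein-coating geometries (bare metal, protein on top only, or
conformal protein covering top and sidewalls) to produce the piecewise-
constant permittivity stack consumed by the RCWA solver.

Conventions
-----------
* x is periodic with period ``period`` (default 1 µm) sampled on
  ``n_columns`` equal-width cells (default 200, i.e. 5 nm resolution).
* z = 0 is the top of the uniform gold base; slices are ordered from the
  substrate side towards the ambient side.
* All lengths are in nanometres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

__all__ = [
    "SUBSTRATE",
    "METAL",
    "ANALYTE",
    "AMBIENT",
    "MaterialSet",
    "RoughnessSpec",
    "SurfaceProfile",
    "CoatingModel",
    "LayerStack",
    "generate_rough_profile",
    "build_layer_stack",
    "uniform_stack",
    "protein_area_increment",
]

# Material indices used throughout the package.
SUBSTRATE, METAL, ANALYTE, AMBIENT = 0, 1, 2, 3

#: Nominal total gold thickness of the sensor (uniform base + rough layer).
DEFAULT_TOTAL_METAL_NM = 50.0


@dataclass(frozen=True)
class MaterialSet:
    """Refractive indices of the four media of the Kretschmann sensor.

    Defaults are the HeNe (633 nm) values used throughout: BK7 glass
    substrate, gold film, BSA protein analyte (80 mg/mL) and water ambient.
    """

    n_substrate: float = 1.52
    n_metal: complex = 0.18 + 3.43j
    n_analyte: float = 1.35
    n_ambient: float = 1.33

    def __post_init__(self) -> None:
        nm = complex(self.n_metal)
        if nm.imag <= 0:
            raise ValueError(
                "n_metal must have a positive imaginary part (absorbing metal "
                "under the e^{-i omega t} convention)"
            )
        for name in ("n_substrate", "n_analyte", "n_ambient"):
            if float(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")
        if nm.real <= 0:
            raise ValueError("Re(n_metal) must be positive")

    @property
    def refractive_indices(self) -> np.ndarray:
        """Indices ordered as (substrate, metal, analyte, ambient)."""
        return np.array(
            [self.n_substrate, self.n_metal, self.n_analyte, self.n_ambient],
            dtype=complex,
        )

    @property
    def permittivities(self) -> np.ndarray:
        return self.refractive_indices**2


@dataclass(frozen=True)
class RoughnessSpec:
    """Parameters of one Gaussian random rough surface realization."""

    h: float
    cl: float
    n_columns: int = 200
    period: float = 1000.0
    slice_thickness: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("maximum roughness height h must be >= 0")
        if self.cl <= 0:
            raise ValueError("correlation length cl must be > 0")
        if self.n_columns < 2:
            raise ValueError("n_columns must be >= 2")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        if self.cl < self.lateral_resolution:
            raise ValueError(
                f"cl={self.cl} nm is below the lateral resolution "
                f"{self.lateral_resolution} nm of the {self.n_columns}-column grid"
            )

    @property
    def lateral_resolution(self) -> float:
        """Width of one column cell in nm."""
        return self.period / self.n_columns


@dataclass(frozen=True)
class SurfaceProfile:
    """Column heights (nm) of one rough unit cell above the gold base."""

    heights: np.ndarray
    period: float
    spec: RoughnessSpec

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "heights", np.asarray(self.heights, dtype=float)
        )
        if self.heights.ndim != 1:
            raise ValueError("heights must be one-dimensional")
        if np.any(self.heights < -1e-12):
            raise ValueError("heights must be non-negative")

    @property
    def x_nm(self) -> np.ndarray:
        """Left edge of each column cell."""
        n = self.heights.size
        return np.arange(n) * (self.period / n)

    @property
    def rms(self) -> float:
        """RMS roughness about the mean height."""
        return float(np.sqrt(np.mean((self.heights - self.heights.mean()) ** 2)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column_index": np.arange(self.heights.size),
                "x_nm": self.x_nm,
                "height_nm": self.heights,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, group) -> None:
        """Write into an open ``h5py`` group."""
        group.create_dataset("heights", data=self.heights)
        for f in dataclasses.fields(self.spec):
            group.attrs[f.name] = getattr(self.spec, f.name)
        group.attrs["period"] = self.period


@dataclass(frozen=True)
class CoatingModel:
    """Protein-coating geometry applied on top of the rough metal.

    ``bare``      no analyte at all (reference/water spectrum);
    ``top_only``  analyte layer following the surface vertically, sidewalls
                  uncoated (fixed protein amount, isolates the LSPR effect);
    ``conformal`` analyte within distance ``d_analyte`` of the metal,
                  sidewalls coated (protein amount grows with roughness).
    """

    tag: str
    d_analyte: float = 5.0

    TAGS = ("bare", "top_only", "conformal")

    def __post_init__(self) -> None:
        if self.tag not in self.TAGS:
            raise ValueError(f"tag must be one of {self.TAGS}, got {self.tag!r}")
        if self.d_analyte < 0:
            raise ValueError("d_analyte must be >= 0")

    @property
    def thickness(self) -> float:
        return 0.0 if self.tag == "bare" else self.d_analyte


@dataclass
class LayerStack:
    """z-sliced, x-periodic piecewise-constant material description.

    ``slices`` runs from the substrate side to the ambient side; each entry
    is ``(thickness_nm, material_row)`` with ``material_row`` an integer
    array of per-column material indices.  The substrate and ambient are
    semi-infinite and not part of ``slices``.
    """

    slices: list
    materials: MaterialSet
    period: float
    substrate_material: int = SUBSTRATE
    ambient_material: int = AMBIENT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = []
        n_cols = None
        for thickness, row in self.slices:
            if thickness <= 0:
                raise ValueError("slice thickness must be > 0")
            row = np.asarray(row, dtype=np.int8)
            if row.ndim != 1:
                raise ValueError("material rows must be 1-D")
            if n_cols is None:
                n_cols = row.size
            elif row.size != n_cols:
                raise ValueError("all material rows must have equal length")
            if row.min() < 0 or row.max() > AMBIENT:
                raise ValueError("invalid material index in slice")
            cleaned.append((float(thickness), row))
        self.slices = cleaned

    @property
    def n_columns(self) -> int:
        return self.slices[0][1].size if self.slices else 1

    @property
    def total_thickness(self) -> float:
        return float(sum(t for t, _ in self.slices))

    def is_uniform(self) -> bool:
        return all(np.all(row == row[0]) for _, row in self.slices)

    def merged(self) -> "LayerStack":
        """Merge consecutive slices with identical material rows (exact)."""
        merged: list = []
        for thickness, row in self.slices:
            if merged and np.array_equal(merged[-1][1], row):
                merged[-1][0] += thickness
            else:
                merged.append([thickness, row])
        return LayerStack(
            [(t, r) for t, r in merged],
            self.materials,
            self.period,
            self.substrate_material,
            self.ambient_material,
            dict(self.meta),
        )

    def eps_rows(self) -> list:
        """Per-slice complex permittivity rows."""
        eps = self.materials.permittivities
        return [(t, eps[row]) for t, row in self.slices]

    def material_area(self, material: int) -> float:
        """Cross-sectional area (nm²) of one material within the slices."""
        dx = self.period / self.n_columns
        return float(
            sum(t * dx * np.count_nonzero(row == material) for t, row in self.slices)
        )

    def to_hdf5(self, group) -> None:
        group.create_dataset(
            "thicknesses", data=np.array([t for t, _ in self.slices])
        )
        group.create_dataset(
            "material_index",
            data=np.stack([row for _, row in self.slices])
            if self.slices
            else np.zeros((0, self.n_columns), dtype=np.int8),
        )
        group.create_dataset(
            "refractive_indices", data=self.materials.refractive_indices
        )
        group.attrs["period"] = self.period
        group.attrs["substrate_material"] = self.substrate_material
        group.attrs["ambient_material"] = self.ambient_material


def generate_rough_profile(
    spec: RoughnessSpec, quantize: bool = False
) -> SurfaceProfile:
    """Draw one Gaussian random rough surface.

    Pipeline: i.i.d. fair binary column sequence, scaled by ``h``; discrete
    Fourier transform; multiplication by the Gaussian low-pass filter
    ``G(k) = exp(-k^2 cl^2 / 8)`` (angular spatial frequency ``k``, giving a
    Gaussian surface autocorrelation ``exp(-x^2/cl^2)``); inverse transform;
    minimum shifted to zero and span rescaled to exactly ``h``.

    With ``quantize=True`` the filtered profile is re-quantized to the two
    levels {0, h} at its median (a correlated telegraph surface with ~0.5
    metal fill and vertical sidewalls).  The default keeps the continuous
    filtered heights; see the methods note for the trade-offs between the
    two readings of the construction.

    A filter wide enough to pass only the DC term (``cl`` far beyond the
    period) leaves a constant profile, which is returned as an all-zero
    (flat) surface rather than renormalized noise.
    """
    rng = np.random.default_rng(spec.seed)
    bits = rng.integers(0, 2, spec.n_columns).astype(float)
    signal = spec.h * bits
    spectrum = np.fft.fft(signal)
    k = 2.0 * np.pi * np.fft.fftfreq(spec.n_columns, d=spec.lateral_resolution)
    spectrum *= np.exp(-(k**2) * spec.cl**2 / 8.0)
    profile = np.fft.ifft(spectrum).real
    span = profile.max() - profile.min()
    if spec.h > 0 and span > 1e-9 * spec.h:
        if quantize:
            profile = np.where(profile > np.median(profile), spec.h, 0.0)
        else:
            profile = (profile - profile.min()) * (spec.h / span)
    else:
        profile = np.zeros_like(profile)
    return SurfaceProfile(profile, spec.period, spec)


def _material_grid(
    profile: SurfaceProfile, coating: CoatingModel, slice_thickness: float
) -> tuple[np.ndarray, float]:
    """Discretize the rough + coating region onto the (column, slice) grid.

    Returns ``(grid, dz)`` with ``grid`` of shape (n_slices, n_columns)
    holding material indices, ordered bottom (z=0) to top.
    """
    dz = float(slice_thickness)
    heights = profile.heights
    n_cols = heights.size
    dx = profile.period / n_cols
    top = heights.max() + coating.thickness
    n_z = int(np.ceil(top / dz - 1e-9))
    if n_z == 0:
        return np.zeros((0, n_cols), dtype=np.int8), dz
    z_mid = (np.arange(n_z) + 0.5) * dz
    metal = z_mid[:, None] < heights[None, :]
    grid = np.full((n_z, n_cols), AMBIENT, dtype=np.int8)
    grid[metal] = METAL
    d = coating.thickness
    if coating.tag == "top_only" and d > 0:
        offset = z_mid[:, None] - heights[None, :]
        grid[(offset >= 0) & (offset < d)] = ANALYTE
    elif coating.tag == "conformal" and d > 0:
        # Morphological dilation of the metal by a Euclidean disk of radius
        # d on the (dx x dz) grid.  The profile is tiled three times in x to
        # honour periodicity and one metal row is appended at the bottom so
        # that the semi-infinite gold base coats flat regions too.
        tiled = np.concatenate([~metal] * 3, axis=1)
        tiled = np.concatenate(
            [np.zeros((1, tiled.shape[1]), dtype=bool), tiled], axis=0
        )
        dist = distance_transform_edt(tiled, sampling=(dz, dx))
        dist = dist[1:, n_cols : 2 * n_cols]
        grid[(~metal) & (dist <= d + 1e-9)] = ANALYTE
    # drop trailing rows that are pure ambient (they belong to the
    # semi-infinite cover and would only add degenerate interfaces)
    keep = np.where(~np.all(grid == AMBIENT, axis=1))[0]
    n_keep = int(keep[-1]) + 1 if keep.size else 0
    return grid[:n_keep], dz


def build_layer_stack(
    profile: SurfaceProfile,
    materials: MaterialSet,
    coating: CoatingModel,
    base_metal_thickness: float | None = None,
    total_metal_thickness: float = DEFAULT_TOTAL_METAL_NM,
) -> LayerStack:
    """Assemble substrate / uniform gold / rough region / ambient stack.

    The uniform gold base is ``total_metal_thickness - h`` nm thick by
    default, so the nominal gold budget (50 nm) is split between the base
    and the rough layer of depth ``h``.
    """
    h = profile.spec.h
    if base_metal_thickness is None:
        base_metal_thickness = total_metal_thickness - h
    if base_metal_thickness < 0:
        raise ValueError(
            f"h={h} nm exceeds the total metal thickness "
            f"{total_metal_thickness} nm (negative base thickness)"
        )
    n_cols = profile.heights.size
    slices: list = []
    if base_metal_thickness > 0:
        slices.append(
            (base_metal_thickness, np.full(n_cols, METAL, dtype=np.int8))
        )
    grid, dz = _material_grid(profile, coating, profile.spec.slice_thickness)
    slices.extend((dz, row) for row in grid)
    return LayerStack(
        slices,
        materials,
        profile.period,
        meta={
            "h": h,
            "cl": profile.spec.cl,
            "seed": profile.spec.seed,
            "coating": coating.tag,
            "d_analyte": coating.thickness,
            "slice_thickness": dz,
        },
    )


def uniform_stack(
    materials: MaterialSet,
    metal_thickness: float = DEFAULT_TOTAL_METAL_NM,
    analyte_thickness: float = 0.0,
    period: float = 1000.0,
    n_columns: int = 1,
) -> LayerStack:
    """Laterally uniform substrate/metal[/analyte]/ambient stack.

    This is the ideal smooth-sensor baseline and the input of the
    transfer-matrix Fresnel oracle.
    """
    if metal_thickness < 0 or analyte_thickness < 0:
        raise ValueError("thicknesses must be >= 0")
    slices = []
    if metal_thickness > 0:
        slices.append((metal_thickness, np.full(n_columns, METAL, np.int8)))
    if analyte_thickness > 0:
        slices.append((analyte_thickness, np.full(n_columns, ANALYTE, np.int8)))
    return LayerStack(
        slices,
        materials,
        period,
        meta={"uniform": True, "metal_thickness": metal_thickness,
              "analyte_thickness": analyte_thickness},
    )


def protein_area_increment(profile: SurfaceProfile, d_analyte: float) -> float:
    """Percent increase of analyte cross-section of the conformal coating
    over the top-only coating, counted on the discretized grid."""
    if d_analyte <= 0:
        raise ValueError("d_analyte must be > 0")
    dz = profile.spec.slice_thickness
    dx = profile.period / profile.heights.size
    top, _ = _material_grid(profile, CoatingModel("top_only", d_analyte), dz)
    conf, _ = _material_grid(profile, CoatingModel("conformal", d_analyte), dz)
    area_top = np.count_nonzero(top == ANALYTE) * dx * dz
    area_conf = np.count_nonzero(conf == ANALYTE) * dx * dz
    return 100.0 * (area_conf - area_top) / area_top
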