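"""Rough-surface generation and layer-stack construction."""

import numpy as np
import pytest

from roughspr.structure_builder import (
    AMBIENT,
    ANALYTE,
    METAL,
    CoatingModel,
    MaterialSet,
    RoughnessSpec,
    SurfaceProfile,
    _material_grid,
    build_layer_stack,
    generate_rough_profile,
    protein_area_increment,
    uniform_stack,
)


def spec(h, cl, seed=0, **kw):
    return RoughnessSpec(h=h, cl=cl, seed=seed, **kw)


class TestGenerateRoughProfile:
    def test_seed_reproducibility_is_bit_exact(self):
        a = generate_rough_profile(spec(10, 20, seed=7))
        b = generate_rough_profile(spec(10, 20, seed=7))
        assert np.array_equal(a.heights, b.heights)
        c = generate_rough_profile(spec(10, 20, seed=8))
        assert not np.array_equal(a.heights, c.heights)

    @pytest.mark.parametrize("h,cl", [(2, 5), (10, 20), (20, 5), (20, 50)])
    @pytest.mark.parametrize("quantize", [False, True])
    def test_span_and_bounds(self, h, cl, quantize):
        p = generate_rough_profile(spec(h, cl, seed=3), quantize=quantize)
        assert p.heights.size == 200
        assert p.heights.min() == pytest.approx(0.0, abs=1e-12)
        assert p.heights.max() - p.heights.min() == pytest.approx(h, rel=1e-12)
        assert np.all(p.heights <= h + 1e-9)

    def test_quantized_profile_is_two_level(self):
        p = generate_rough_profile(spec(10, 20, seed=3), quantize=True)
        assert set(np.unique(p.heights)) == {0.0, 10.0}
        # median threshold keeps the metal fill balanced
        assert abs(np.mean(p.heights > 0) - 0.5) <= 0.01

    def test_zero_height_is_flat(self):
        p = generate_rough_profile(spec(0, 20, seed=1))
        assert np.all(p.heights == 0.0)

    def test_dc_only_filter_gives_flat_surface(self):
        # cl far beyond the period: the Gaussian filter passes only the DC
        # term, recovering the theoretical uniform surface
        p = generate_rough_profile(spec(10, 1e6, seed=7))
        assert np.all(p.heights == 0.0)

    def test_ensemble_rms_monotone_in_h(self):
        means = []
        for h in (2, 5, 10, 20):
            rms = [
                generate_rough_profile(spec(h, 20, seed=s)).rms
                for s in range(50)
            ]
            means.append(np.mean(rms))
        assert np.all(np.diff(means) > 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"h": -1, "cl": 20},
            {"h": 5, "cl": 0},
            {"h": 5, "cl": -3},
            {"h": 5, "cl": 2},  # below the 5 nm lateral resolution
            {"h": 5, "cl": 20, "n_columns": 1},
            {"h": 5, "cl": 20, "slice_thickness": 0},
        ],
    )
    def test_invalid_spec_raises(self, kwargs):
        with pytest.raises(ValueError):
            RoughnessSpec(seed=0, **kwargs)


class TestUniformStack:
    def test_layer_counts(self, materials):
        assert len(uniform_stack(materials, 50, 0).slices) == 1
        assert len(uniform_stack(materials, 50, 5).slices) == 2
        assert len(uniform_stack(materials, 0, 0).slices) == 0

    def test_zero_analyte_equals_bare(self, materials):
        bare = uniform_stack(materials, 50, 0)
        zero = uniform_stack(materials, 50, 0.0)
        assert len(bare.slices) == len(zero.slices)
        for (t1, r1), (t2, r2) in zip(bare.slices, zero.slices):
            assert t1 == t2 and np.array_equal(r1, r2)

    def test_negative_thickness_raises(self, materials):
        with pytest.raises(ValueError):
            uniform_stack(materials, -1, 0)


class TestBuildLayerStack:
    def test_flat_profile_coating_models_identical(self, materials):
        p = generate_rough_profile(spec(0, 20))
        top = build_layer_stack(p, materials, CoatingModel("top_only"))
        conf = build_layer_stack(p, materials, CoatingModel("conformal"))
        assert len(top.slices) == len(conf.slices)
        for (t1, r1), (t2, r2) in zip(top.slices, conf.slices):
            assert t1 == t2 and np.array_equal(r1, r2)

    def test_rough_region_slice_count(self, materials):
        p = generate_rough_profile(spec(20, 10, slice_thickness=0.1))
        stack = build_layer_stack(p, materials, CoatingModel("bare"))
        rough = [t for t, _ in stack.slices[1:]]
        assert len(rough) == 200  # 20 nm at 0.1 nm per slice
        assert sum(rough) == pytest.approx(20.0)
        assert stack.slices[0][0] == pytest.approx(30.0)  # 50 - h base

    def test_excessive_height_raises(self, materials):
        p = generate_rough_profile(spec(20, 10))
        with pytest.raises(ValueError):
            build_layer_stack(p, materials, CoatingModel("bare"),
                              total_metal_thickness=15.0)

    def test_square_ridge_conformal_coats_sidewalls(self, materials):
        # single vertical-walled ridge: the conformal model must place
        # analyte laterally adjacent to the walls above the top-only band,
        # the top-only model must not
        heights = np.where((np.arange(200) >= 50) & (np.arange(200) < 100),
                           15.0, 0.0)
        p = SurfaceProfile(heights, 1000.0, spec(15, 20, slice_thickness=0.5))
        top, dz = _material_grid(p, CoatingModel("top_only", 5.0), 0.5)
        conf, _ = _material_grid(p, CoatingModel("conformal", 5.0), 0.5)
        # column 49 sits beside the left wall; z in (d, h) is beyond the
        # flat-region coating band but within reach of the wall
        iz = int(10.0 / dz)  # z = 10 nm, between d=5 and h=15
        assert top[iz, 49] == AMBIENT
        assert conf[iz, 49] == ANALYTE
        assert conf[iz, 50] == METAL

    def test_conformal_area_never_below_top_only(self, materials):
        for s in range(8):
            p = generate_rough_profile(spec(12, 8, seed=s, slice_thickness=0.5))
            top = build_layer_stack(p, materials, CoatingModel("top_only"))
            conf = build_layer_stack(p, materials, CoatingModel("conformal"))
            assert (
                conf.material_area(ANALYTE) >= top.material_area(ANALYTE) - 1e-9
            )
        flat = generate_rough_profile(spec(0, 20))
        tf = build_layer_stack(flat, materials, CoatingModel("top_only"))
        cf = build_layer_stack(flat, materials, CoatingModel("conformal"))
        assert cf.material_area(ANALYTE) == pytest.approx(
            tf.material_area(ANALYTE)
        )

    def test_metal_area_independent_of_slice_thickness(self, materials):
        p_fine = generate_rough_profile(spec(10, 20, seed=2,
                                             slice_thickness=0.1))
        p_coarse = generate_rough_profile(spec(10, 20, seed=2,
                                               slice_thickness=0.5))
        a_fine = build_layer_stack(
            p_fine, materials, CoatingModel("bare")
        ).material_area(METAL)
        a_coarse = build_layer_stack(
            p_coarse, materials, CoatingModel("bare")
        ).material_area(METAL)
        # discretization moves at most one cell per column
        budget = 200 * 5.0 * 0.5
        assert abs(a_fine - a_coarse) <= budget

    def test_merged_preserves_total_thickness(self, materials):
        p = generate_rough_profile(spec(10, 20, seed=2, slice_thickness=0.5))
        stack = build_layer_stack(p, materials, CoatingModel("conformal"))
        merged = stack.merged()
        assert merged.total_thickness == pytest.approx(stack.total_thickness)
        assert merged.material_area(METAL) == pytest.approx(
            stack.material_area(METAL)
        )


def _brute_force_increment(heights, period, d, dz):
    """Independent pixel-count oracle for the sidewall protein increment.

    Explicit O(N^2) Euclidean dilation of the metal mask (tiled for
    periodicity, gold base included), compared cell-center to cell-center
    exactly like the production dilation rule.
    """
    n = heights.size
    dx = period / n
    n_z = int(np.ceil((heights.max() + d) / dz - 1e-9))
    z = (np.arange(n_z) + 0.5) * dz
    metal = z[:, None] < heights[None, :]
    top = 0
    conf = 0
    # metal cell centres of the tiled pattern plus one base row
    pts = []
    for c in range(3 * n):
        hc = heights[c % n]
        for iz in range(n_z):
            if z[iz] < hc:
                pts.append(((c - n) * dx, z[iz]))
        pts.append(((c - n) * dx, -dz / 2))  # gold base below z = 0
    pts = np.array(pts)
    for c in range(n):
        for iz in range(n_z):
            if metal[iz, c]:
                continue
            if 0 <= z[iz] - heights[c] < d:
                top += 1
            dist = np.min(
                np.hypot(pts[:, 0] - c * dx, pts[:, 1] - z[iz])
            )
            if dist <= d + 1e-9:
                conf += 1
    return 100.0 * (conf - top) / top


class TestProteinAreaIncrement:
    def test_flat_profile_has_no_increment(self):
        p = generate_rough_profile(spec(0, 20))
        assert protein_area_increment(p, 5.0) == pytest.approx(0.0)

    def test_square_wave_matches_pixel_count_oracle(self):
        # one 50 nm wide, 10 nm tall ridge on a 100 nm cell (fill 0.5)
        heights = np.where(np.arange(20) < 10, 10.0, 0.0)
        p = SurfaceProfile(
            heights, 100.0,
            RoughnessSpec(h=10, cl=20, n_columns=20, period=100.0,
                          slice_thickness=0.5, seed=0),
        )
        expected = _brute_force_increment(heights, 100.0, 5.0, 0.5)
        assert protein_area_increment(p, 5.0) == pytest.approx(expected)

    def test_random_profile_matches_pixel_count_oracle(self):
        p = generate_rough_profile(
            RoughnessSpec(h=12, cl=10, n_columns=20, period=100.0,
                          slice_thickness=0.5, seed=5)
        )
        expected = _brute_force_increment(p.heights, 100.0, 5.0, 0.5)
        assert protein_area_increment(p, 5.0) == pytest.approx(expected)

    def test_ensemble_increment_grows_with_height_at_small_cl(self):
        means = []
        for h in (5, 12, 20):
            inc = [
                protein_area_increment(
                    generate_rough_profile(
                        spec(h, 5, seed=s, slice_thickness=0.5)
                    ),
                    5.0,
                )
                for s in range(10)
            ]
            means.append(np.mean(inc))
        assert means[0] < means[1] < means[2]

    def test_zero_thickness_raises(self):
        p = generate_rough_profile(spec(5, 20))
        with pytest.raises(ValueError):
            protein_area_increment(p, 0.0)


class TestSerialization:
    def test_profile_csv_roundtrip(self, tmp_path):
        import pandas as pd

        p = generate_rough_profile(spec(10, 20, seed=4))
        path = tmp_path / "profile.csv"
        p.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["column_index", "x_nm", "height_nm"]
        np.testing.assert_allclose(df["height_nm"].to_numpy(), p.heights)

    def test_hdf5_roundtrip(self, tmp_path, materials):
        import h5py

        p = generate_rough_profile(spec(10, 20, seed=4))
        stack = build_layer_stack(p, materials, CoatingModel("conformal"))
        path = tmp_path / "run.h5"
        with h5py.File(path, "w") as fh:
            p.to_hdf5(fh.create_group("profile"))
            stack.to_hdf5(fh.create_group("stack"))
        with h5py.File(path) as fh:
            np.testing.assert_allclose(fh["profile/heights"][:], p.heights)
            assert fh["profile"].attrs["seed"] == 4
            assert fh["stack/material_index"].shape[1] == 200


class TestMaterialSet:
    def test_defaults_are_sensor_constants(self, materials):
        assert materials.n_substrate == 1.52
        assert materials.n_metal == 0.18 + 3.43j
        assert materials.n_analyte == 1.35
        assert materials.n_ambient == 1.33

    def test_gain_metal_rejected(self):
        with pytest.raises(ValueError):
            MaterialSet(n_metal=0.18 - 3.43j)
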