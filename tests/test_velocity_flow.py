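"""Velocity-field fitting, integration, inversion and warping."""

import numpy as np
import pytest

from velflow import (
    BSplineConfig,
    DisplacementField,
    FitConfig,
    FlowSpec,
    GridGeometry,
    NumericalError,
    PointSet,
    PointSetSeries,
    ValidationError,
    VelocityField,
    fit_displacement_between_point_sets,
    fit_velocity_flow,
    generate_flow_series,
    integrate_velocity_field,
    interpolate_vector_field,
    invert_displacement_field,
    transform_image_in_time,
    transform_points_in_time,
)
from velflow.velocity_flow import _bracket


def constant_velocity(geom, c, n_slices=3):
    data = np.tile(np.asarray(c, dtype=np.float32),
                   (n_slices,) + geom.size + (1,))
    return VelocityField(geom, data)


@pytest.fixture(scope="module")
def small_geom():
    return GridGeometry((32, 32, 32), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


@pytest.fixture(scope="module")
def translation_fit(small_geom):
    """Fitted flow for a known pure translation (shared across tests)."""
    spec = FlowSpec(kind="translation", n_points=100, n_times=2,
                    translation=(2.0, 0.0, 0.0), seed=7)
    series, _ = generate_flow_series(spec, small_geom)
    cfg = FitConfig(n_integration_points=3, max_iterations=60)
    field, trace = fit_velocity_flow(series, small_geom, cfg)
    return series, field, trace


class TestBracketing:
    def test_interior_tie_uses_left_interval(self):
        times = np.array([0.0, 0.25, 0.6, 1.0])
        assert _bracket(times, 0.25) == (0, 1)
        assert _bracket(times, 0.6) == (1, 2)

    def test_endpoints_use_first_and_last_interval(self):
        times = np.array([0.0, 0.5, 1.0])
        assert _bracket(times, 0.0) == (0, 1)
        assert _bracket(times, 1.0) == (1, 2)

    def test_strict_interior(self):
        times = np.array([0.0, 0.5, 1.0])
        assert _bracket(times, 0.3) == (0, 1)
        assert _bracket(times, 0.7) == (1, 2)


class TestIntegration:
    def test_empty_interval_is_zero(self, small_geom, rng):
        data = rng.normal(size=(3,) + small_geom.size + (3,)).astype(
            np.float32)
        v = VelocityField(small_geom, data)
        d = integrate_velocity_field(v, 0.4, 0.4)
        assert np.all(d.vectors == 0)

    def test_constant_flow_is_exact(self, small_geom):
        c = np.array([1.5, -0.5, 0.75])
        v = constant_velocity(small_geom, c)
        for t0, t1 in [(0.0, 1.0), (1.0, 0.0), (0.2, 0.7)]:
            d = integrate_velocity_field(v, t0, t1, substeps=3)
            assert np.allclose(d.vectors, c * (t1 - t0), atol=1e-5)

    def test_time_linear_velocity_integrates_to_half(self, small_geom):
        n = 11
        data = np.zeros((n,) + small_geom.size + (3,), np.float32)
        for i, t in enumerate(np.linspace(0, 1, n)):
            data[i, ..., 0] = t
        v = VelocityField(small_geom, data)
        d = integrate_velocity_field(v, 0.0, 1.0)
        assert np.abs(d.vectors[..., 0] - 0.5).max() <= 1e-3
        assert np.abs(d.vectors[..., 1:]).max() <= 1e-6

    def test_second_order_convergence_in_substeps(self, small_geom):
        """Global error of the midpoint scheme shrinks as O(h^2)."""
        a, c = 0.1, np.full(3, 15.5)
        centers = small_geom.voxel_centers()
        data = np.tile((a * (centers - c)).astype(np.float32), (2, 1, 1, 1, 1))
        v = VelocityField(small_geom, data)
        pts = PointSet(np.array([[10.0, 12.0, 20.0], [20.0, 8.0, 14.0]]))
        exact = c + (pts.coords - c) * np.exp(a)
        substeps = np.array([1, 2, 4, 8, 16])
        errs = [np.abs(transform_points_in_time(pts, v, 0, 1, s).coords
                       - exact).max() for s in substeps]
        slope = np.polyfit(np.log(substeps), np.log(errs), 1)[0]
        assert -2.3 <= slope <= -1.7

    def test_time_outside_domain_rejected(self, small_geom):
        v = constant_velocity(small_geom, [0, 0, 0])
        with pytest.raises(ValidationError):
            integrate_velocity_field(v, -0.1, 1.0)


class TestPointTransforms:
    def test_zero_field_is_identity(self, small_geom, rng):
        v = VelocityField.zeros(small_geom, 3)
        ps = PointSet(rng.uniform(5, 25, (20, 3)))
        out = transform_points_in_time(ps, v, 0.0, 1.0)
        assert np.array_equal(out.coords, ps.coords)
        assert out.ids == ps.ids

    def test_constant_flow_translates(self, small_geom, rng):
        c = np.array([1.0, 2.0, -1.0])
        v = constant_velocity(small_geom, c)
        ps = PointSet(rng.uniform(8, 22, (20, 3)))
        out = transform_points_in_time(ps, v, 0.0, 1.0)
        assert np.allclose(out.coords, ps.coords + c, atol=1e-5)

    def test_round_trip_on_fitted_field(self, translation_fit):
        series, field, _ = translation_fit
        fwd = transform_points_in_time(series.sets[0], field, 0.0, 1.0)
        back = transform_points_in_time(fwd, field, 1.0, 0.0)
        err = np.linalg.norm(back.coords - series.sets[0].coords, axis=1)
        assert err.mean() < 0.1  # voxel spacing is 1


class TestFlowFit:
    def test_zero_motion_identity(self, geom2d, rng):
        base = PointSet(rng.uniform(geom2d.lower + 3, geom2d.upper - 3,
                                    (50, 2)))
        series = PointSetSeries((base, base, base),
                                np.array([0.0, 0.4, 1.0]))
        cfg = FitConfig(n_integration_points=3, max_iterations=5)
        field, trace = fit_velocity_flow(series, geom2d, cfg)
        assert np.abs(field.data).max() <= 1e-9
        assert np.all(trace.average_error == 0.0)
        assert np.all(trace.median_error == 0.0)

    def test_translation_recovery(self, translation_fit):
        series, field, trace = translation_fit
        moved = transform_points_in_time(series.sets[0], field, 0.0, 1.0)
        err = np.linalg.norm(moved.coords - series.sets[1].coords, axis=1)
        w = series.sets[0].weights
        assert np.sum(w * err) / w.sum() <= 0.1 * 2.0
        # mid-trajectory close to the half translation
        mid = transform_points_in_time(series.sets[0], field, 0.0, 0.5)
        half = series.sets[0].coords + np.array([1.0, 0.0, 0.0])
        assert np.linalg.norm(mid.coords - half, axis=1).mean() <= 0.2 * 2.0

    def test_trace_running_minimum_non_increasing(self, translation_fit):
        _, _, trace = translation_fit
        assert np.all(np.isfinite(trace.average_error))
        running = np.minimum.accumulate(trace.average_error)
        assert np.all(np.diff(running) <= 0)

    def test_semigroup_composition(self, translation_fit, small_geom):
        _, field, _ = translation_fit
        direct = transform_points_in_time(
            PointSet(np.array([[12.0, 15.0, 18.0], [20.0, 10.0, 14.0]])),
            field, 0.0, 1.0)
        half = transform_points_in_time(
            PointSet(np.array([[12.0, 15.0, 18.0], [20.0, 10.0, 14.0]])),
            field, 0.0, 0.5)
        stitched = transform_points_in_time(half, field, 0.5, 1.0)
        err = np.linalg.norm(stitched.coords - direct.coords, axis=1)
        assert err.mean() <= 0.2

    def test_dimension_mismatch_rejected(self, geom2d, rng):
        base = PointSet(rng.uniform(2, 10, (10, 3)))
        series = PointSetSeries((base, base), np.array([0.0, 1.0]))
        with pytest.raises(ValidationError):
            fit_velocity_flow(series, geom2d, FitConfig(max_iterations=1))

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            FitConfig(n_integration_points=1)
        with pytest.raises(ValidationError):
            FitConfig(step_size=0.0)


class TestInversion:
    def test_zero_field_inverts_to_zero(self, geom3d):
        inv = invert_displacement_field(DisplacementField.zeros(geom3d))
        assert np.all(inv.vectors == 0)

    def test_constant_translation_inverts_to_negation(self, small_geom):
        c = np.array([1.2, -0.8, 0.5], dtype=np.float32)
        d = DisplacementField(small_geom, np.tile(c, small_geom.size + (1,)))
        inv = invert_displacement_field(d, max_iterations=100,
                                        tolerance=1e-6)
        centers = small_geom.voxel_centers()
        interior = np.all((centers >= 4) & (centers <= 27), axis=-1)
        assert np.allclose(inv.vectors[interior], -c, atol=1e-3)

    def test_sinusoidal_composition_residual_small(self, small_geom):
        centers = small_geom.voxel_centers()
        vec = np.zeros(small_geom.size + (3,))
        vec[..., 0] = 0.6 * np.sin(2 * np.pi * centers[..., 0] / 32)
        vec[..., 1] = 0.4 * np.sin(2 * np.pi * centers[..., 2] / 32)
        d = DisplacementField(small_geom, vec)
        inv = invert_displacement_field(d, max_iterations=200,
                                       tolerance=1e-6)
        x = centers.reshape(-1, 3)
        y = x + d.vectors.reshape(-1, 3)
        comp = y + interpolate_vector_field(inv, y) - x
        interior = np.all((x >= 4) & (x <= 27), axis=1)
        assert np.linalg.norm(comp, axis=1)[interior].mean() < 0.05

    def test_divergence_raises(self, small_geom):
        # fixed-point map has Lipschitz constant > 1: updates grow steadily
        centers = small_geom.voxel_centers()
        vec = -1.1 * (centers - 15.5)
        d = DisplacementField(small_geom, vec.astype(np.float32))
        with pytest.raises(NumericalError):
            invert_displacement_field(d, max_iterations=100, tolerance=1e-9)


class TestImageWarp:
    def test_zero_field_is_identity(self, geom3d, rng):
        v = VelocityField.zeros(geom3d, 2)
        img = rng.uniform(size=geom3d.size)
        assert np.allclose(transform_image_in_time(img, v, 0, 1), img)

    def test_blob_centroid_moves_with_constant_flow(self, small_geom):
        from velflow import generate_blob_image

        c = np.array([3.0, 0.0, 0.0])
        v = constant_velocity(small_geom, c)
        img = generate_blob_image([12.0, 16.0, 16.0], 2.5, small_geom)
        out = transform_image_in_time(img, v, 0.0, 1.0)

        def centroid(im):
            cen = small_geom.voxel_centers()
            return (im[..., None] * cen).sum((0, 1, 2)) / im.sum()

        assert np.linalg.norm(centroid(out) - (centroid(img) + c)) < 1.0

    def test_nearest_warp_invents_no_labels(self, small_geom, rng):
        labels = np.zeros(small_geom.size, dtype=np.int32)
        labels[8:16, 8:16, 8:16] = 4
        labels[18:24, 18:24, 18:24] = 9
        v = constant_velocity(small_geom, [1.7, -2.2, 0.9])
        out = transform_image_in_time(labels, v, 0.0, 1.0,
                                      interpolation="nearest")
        assert set(np.unique(out)) <= set(np.unique(labels))

    def test_geometry_mismatch_rejected(self, small_geom):
        v = VelocityField.zeros(small_geom, 2)
        with pytest.raises(ValidationError):
            transform_image_in_time(np.zeros((4, 4, 4)), v, 0, 1)


class TestPairedPointFit:
    def test_identical_sets_give_zero_field(self, geom3d, rng):
        ps = PointSet(rng.uniform(2, 13, (40, 3)))
        fld = fit_displacement_between_point_sets(ps, ps, geom3d)
        assert np.all(fld.vectors == 0)

    def test_pure_translation_recovered_at_anchors(self, small_geom, rng):
        moving = PointSet(rng.uniform(8, 24, (150, 3)))
        d = np.array([1.5, -1.0, 0.5])
        fixed = moving.with_coords(moving.coords + d)
        fld = fit_displacement_between_point_sets(
            fixed, moving, small_geom, BSplineConfig(levels=5))
        at_anchors = interpolate_vector_field(fld, moving.coords)
        assert np.allclose(at_anchors, d, atol=0.2)

    def test_fitted_field_halves_distance(self, small_geom, rng):
        moving = PointSet(rng.uniform(8, 24, (200, 3)))
        centers = moving.coords
        warp = 1.5 * np.sin(2 * np.pi * centers[:, [1, 2, 0]] / 64)
        fixed = moving.with_coords(centers + warp)
        fld = fit_displacement_between_point_sets(
            fixed, moving, small_geom, BSplineConfig(levels=5))
        moved = moving.coords + interpolate_vector_field(fld, moving.coords)
        before = np.linalg.norm(fixed.coords - moving.coords, axis=1).mean()
        after = np.linalg.norm(fixed.coords - moved, axis=1).mean()
        assert after <= 0.5 * before

    def test_id_mismatch_lists_offenders(self, geom3d):
        a = PointSet(np.zeros((2, 3)), ids=("a", "b"))
        b = PointSet(np.zeros((2, 3)), ids=("a", "c"))
        with pytest.raises(ValidationError, match="c"):
            fit_displacement_between_point_sets(a, b, geom3d)
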