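"""Time-varying velocity-field fitting, integration and inversion.

The central object is a velocity field v(x, t) sampled at N uniformly spaced
"integration points" tau_i = i/(N-1) in normalized time [0, 1].  Fitting
proceeds by coordinate-descent over the integration points: at each tau_i the
two chronologically adjacent point sets are warped to tau_i under the current
field, their residual vectors are converted to velocity units, smoothed into
a field by the multilevel B-spline scattered-data approximation, and added to
slice i after scaling by a small step size.  Integrating the fitted field
between any two times in [0, 1] yields a diffeomorphic mapping (for smooth
fields of moderate magnitude), which can be applied to points or resampled
images, or inverted by fixed-point iteration.

Numerical scheme: trajectories are integrated with a fixed-step midpoint
(second-order Runge-Kutta) rule, a configurable number of substeps per slice
interval; the velocity at intermediate times is interpolated linearly between
the adjacent slices and multilinearly in space (clamped at the domain
boundary).  The midpoint rule is exact for velocities that are constant in
space and at most linear in time; for space-dependent flows its global error
is O(h^2) in the substep size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .bspline_sda import BSplineConfig, fit_scattered_field
from .field_core import (
    DisplacementField,
    GridGeometry,
    PointSet,
    PointSetSeries,
    ValidationError,
    VelocityField,
    interpolate_values,
    interpolate_vector_field,
)

__all__ = [
    "FitConfig",
    "ConvergenceTrace",
    "NumericalError",
    "fit_velocity_flow",
    "integrate_velocity_field",
    "invert_displacement_field",
    "transform_points_in_time",
    "transform_image_in_time",
    "fit_displacement_between_point_sets",
]

logger = logging.getLogger(__name__)


class NumericalError(RuntimeError):
    """A numerical procedure failed to converge or produced non-finite data."""


@dataclass(frozen=True)
class FitConfig:
    """Parameters of the velocity-field optimization.

    Parameters
    ----------
    n_integration_points
        Number N of time slices at which the velocity field is stored and
        updated (default 11).
    step_size
        Gradient-descent style step delta in (0, 1] multiplying each smoothed
        update field before it is added to the current slice (default 0.2).
    max_iterations
        Fixed iteration budget (default 200).
    convergence_tolerance
        Early-stop threshold on the change of the 10-iteration windowed mean
        of the average displacement error.  The default 0 disables early
        stopping so the full budget is always run.
    integration_substeps_per_slice_interval
        Substeps of the midpoint integrator per slice interval (default 4).
    bspline
        Scattered-data-approximation configuration for the per-slice updates.
    """

    n_integration_points: int = 11
    step_size: float = 0.2
    max_iterations: int = 200
    convergence_tolerance: float = 0.0
    integration_substeps_per_slice_interval: int = 4
    bspline: BSplineConfig = dc_field(default_factory=BSplineConfig)

    def __post_init__(self):
        if self.n_integration_points < 2:
            raise ValidationError("n_integration_points must be >= 2")
        if not (0.0 < self.step_size <= 1.0):
            raise ValidationError("step_size must be in (0, 1]")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.convergence_tolerance < 0:
            raise ValidationError("convergence_tolerance must be >= 0")
        if self.integration_substeps_per_slice_interval < 1:
            raise ValidationError("integration substeps must be >= 1")

    def to_dict(self) -> dict:
        b = self.bspline
        return {
            "n_integration_points": self.n_integration_points,
            "step_size": self.step_size,
            "max_iterations": self.max_iterations,
            "convergence_tolerance": self.convergence_tolerance,
            "integration_substeps_per_slice_interval":
                self.integration_substeps_per_slice_interval,
            "bspline": {"order": b.order, "base_mesh": list(b.base_mesh),
                        "levels": b.levels},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        d = dict(d)
        b = d.pop("bspline", None)
        if b is not None:
            d["bspline"] = BSplineConfig(order=b["order"],
                                         base_mesh=tuple(b["base_mesh"]),
                                         levels=b["levels"])
        return cls(**d)


@dataclass(frozen=True)
class ConvergenceTrace:
    """Per-iteration error diagnostics of the fit.

    ``average_error[k]`` is the weighted mean point-residual norm averaged
    over the integration points at iteration k (the convergence statistic);
    ``unweighted_average_error`` is the same without point weights;
    ``median_error[k, i]`` is the median residual norm at integration point i.
    """

    average_error: np.ndarray          # (iterations,)
    median_error: np.ndarray           # (iterations, N)
    unweighted_average_error: np.ndarray  # (iterations,)

    def __post_init__(self):
        a = np.asarray(self.average_error, dtype=float)
        m = np.atleast_2d(np.asarray(self.median_error, dtype=float))
        u = np.asarray(self.unweighted_average_error, dtype=float)
        if not (a.shape[0] == m.shape[0] == u.shape[0]):
            raise ValidationError("trace series must share the iteration axis")
        if np.any(a < 0) or np.any(m < 0) or np.any(u < 0):
            raise ValidationError("displacement errors must be non-negative")
        object.__setattr__(self, "average_error", a)
        object.__setattr__(self, "median_error", m)
        object.__setattr__(self, "unweighted_average_error", u)

    @property
    def n_iterations(self) -> int:
        return self.average_error.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        n = self.median_error.shape[1]
        data = {"iteration": np.arange(self.n_iterations),
                "average_error": self.average_error,
                "unweighted_average_error": self.unweighted_average_error}
        for i in range(n):
            data[f"median_error_slice_{i}"] = self.median_error[:, i]
        return pd.DataFrame(data)

    def to_dict(self) -> dict:
        return {"average_error": self.average_error.tolist(),
                "median_error": self.median_error.tolist(),
                "unweighted_average_error":
                    self.unweighted_average_error.tolist()}


# ---------------------------------------------------------------------------
# trajectory propagation
# ---------------------------------------------------------------------------


def _check_time(t: float) -> float:
    t = float(t)
    if not (0.0 <= t <= 1.0):
        raise ValidationError(f"time {t} outside the normalized domain [0, 1]")
    return t


def _velocity_at(v: VelocityField, coords: np.ndarray, t: float) -> np.ndarray:
    """Velocity at physical positions and normalized time t (clamped)."""
    n = v.n_slices
    s = min(max(t, 0.0), 1.0) * (n - 1)
    i0 = min(int(math.floor(s)), n - 2)
    w = s - i0
    a = interpolate_values(v.data[i0], v.geometry, coords)
    if w == 0.0:
        return a
    b = interpolate_values(v.data[i0 + 1], v.geometry, coords)
    return (1.0 - w) * a + w * b


def _propagate(coords: np.ndarray, v: VelocityField, t0: float, t1: float,
               substeps: int) -> np.ndarray:
    """Midpoint-rule flow of physical positions from time t0 to t1."""
    if t0 == t1:
        return np.array(coords, dtype=float, copy=True)
    n_steps = max(1, math.ceil(abs(t1 - t0) * (v.n_slices - 1) * substeps))
    h = (t1 - t0) / n_steps
    x = np.array(coords, dtype=float, copy=True)
    for k in range(n_steps):
        t = t0 + k * h
        v0 = _velocity_at(v, x, t)
        vm = _velocity_at(v, x + 0.5 * h * v0, t + 0.5 * h)
        x += h * vm
    return x


def transform_points_in_time(points: PointSet, v: VelocityField, t0: float,
                             t1: float, substeps: int = 4) -> PointSet:
    """Flow a point set from normalized time t0 to t1 along the field.

    The trajectory of every point is integrated with the same midpoint
    stepping used for grid integration, but evaluated at the moving point.
    Ids and weights are preserved.
    """
    t0, t1 = _check_time(t0), _check_time(t1)
    return points.with_coords(_propagate(points.coords, v, t0, t1, substeps))


def integrate_velocity_field(v: VelocityField, t0: float, t1: float,
                             substeps: int = 4) -> DisplacementField:
    """Integrate the velocity field into a displacement field from t0 to t1.

    Every voxel center is propagated from t0 to t1 (backwards when
    ``t1 < t0``); the output vector is final position minus start position.
    """
    t0, t1 = _check_time(t0), _check_time(t1)
    geom = v.geometry
    x0 = geom.voxel_centers().reshape(-1, geom.ndim)
    x1 = _propagate(x0, v, t0, t1, substeps)
    disp = (x1 - x0).reshape(geom.size + (geom.ndim,))
    return DisplacementField(geom, disp.astype(np.float32))


# ---------------------------------------------------------------------------
# displacement inversion
# ---------------------------------------------------------------------------


def invert_displacement_field(d: DisplacementField, max_iterations: int = 50,
                              tolerance: float = 1e-3) -> DisplacementField:
    """Invert a displacement field by fixed-point iteration.

    Iterates ``u <- -d(id + u)`` until the mean update norm falls below
    ``tolerance`` (in physical units) or the iteration budget is exhausted.
    Diverging updates (increasing five consecutive iterations) raise a
    :class:`NumericalError` -- the deformation is too large for fixed-point
    inversion.
    """
    geom = d.geometry
    x = geom.voxel_centers().reshape(-1, geom.ndim)
    u = np.zeros_like(x)
    prev_update = np.inf
    n_increase = 0
    for _ in range(max_iterations):
        u_new = -interpolate_values(d.vectors, geom, x + u)
        update = float(np.mean(np.linalg.norm(u_new - u, axis=1)))
        u = u_new
        if update < tolerance:
            break
        n_increase = n_increase + 1 if update > prev_update else 0
        if n_increase >= 5:
            raise NumericalError(
                "displacement inversion diverged; the deformation is too "
                "large -- consider splitting it into smaller steps")
        prev_update = update
    comp = interpolate_values(d.vectors, geom, x + u) + u
    logger.info("inversion composition residual: mean %.3g",
                float(np.mean(np.linalg.norm(comp, axis=1))))
    inv = u.reshape(geom.size + (geom.ndim,)).astype(np.float32)
    return DisplacementField(geom, inv)


# ---------------------------------------------------------------------------
# image warping
# ---------------------------------------------------------------------------


def transform_image_in_time(image: np.ndarray, v: VelocityField, t0: float,
                            t1: float, interpolation: str = "linear",
                            substeps: int = 4) -> np.ndarray:
    """Warp an image living at time t0 into the space of time t1.

    Pull-back convention: for every output voxel x the displacement
    integrated from the *output* time t1 back to the *input* time t0 is used
    to look up the source intensity, ``out(x) = img(x + Phi_{t1->t0}(x) - x)``.

    ``interpolation`` is "linear" or "nearest" (use nearest for label maps so
    no new labels are invented).
    """
    image = np.asarray(image)
    geom = v.geometry
    if image.shape != geom.size:
        raise ValidationError(
            f"image shape {image.shape} does not match the field geometry "
            f"{geom.size}; resample the image first")
    if interpolation not in ("linear", "nearest"):
        raise ValidationError("interpolation must be 'linear' or 'nearest'")
    disp = integrate_velocity_field(v, t1, t0, substeps=substeps)
    x = geom.voxel_centers().reshape(-1, geom.ndim)
    src = x + disp.vectors.reshape(-1, geom.ndim)
    idx = geom.continuous_index(src).T  # (D, n_voxels)
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(image.astype(float), idx, order=order,
                                  mode="grid-constant", cval=0.0)
    out = out.reshape(geom.size)
    return out.astype(image.dtype) if interpolation == "nearest" else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_displacement_between_point_sets(fixed: PointSet, moving: PointSet,
                                        geometry: GridGeometry,
                                        bspline: BSplineConfig | None = None,
                                        ) -> DisplacementField:
    """Single-shot smooth displacement field carrying ``moving`` onto ``fixed``.

    The K = 2, single-time-slice degenerate building block of the flow fit:
    vectors ``fixed_j - moving_j`` anchored at ``moving_j`` are smoothed by
    the scattered-data approximation.  Point sets must share ids.
    """
    if fixed.ids != moving.ids:
        offenders = [a for a, b in zip(fixed.ids, moving.ids) if a != b]
        extra = set(fixed.ids) ^ set(moving.ids)
        raise ValidationError(
            f"point-set ids do not match: {sorted(set(offenders) | extra)[:10]}")
    vectors = fixed.coords - moving.coords
    return fit_scattered_field(moving.coords, vectors, moving.weights,
                               geometry, bspline or BSplineConfig())


def _bracket(times: np.ndarray, tau: float) -> tuple[int, int]:
    """Adjacent series interval [t_a, t_b] containing tau.

    Interior ties resolve to the left interval; tau = 0 and tau = 1 use the
    first and last interval so the endpoint slices still receive updates.
    """
    k = len(times)
    if tau <= times[0]:
        return 0, 1
    if tau >= times[-1]:
        return k - 2, k - 1
    b = int(np.searchsorted(times, tau, side="left"))
    return b - 1, b


def fit_velocity_flow(series: PointSetSeries, geometry: GridGeometry,
                      config: FitConfig | None = None,
                      ) -> tuple[VelocityField, ConvergenceTrace]:
    """Optimize a time-varying velocity field from a corresponding series.

    Starting from v = 0, each iteration loops over the N integration points.
    At tau_i the bracketing pair of point sets is warped to tau_i under the
    current field (forward from the earlier set, backward from the later
    one); the residual between the warped pairs, anchored at their midpoints
    and divided by the bracketing interval length, is smoothed into a field
    by the B-spline scattered-data approximation and added to slice i after
    scaling by the step size.  The procedure is fully deterministic.

    Returns the fitted field and a :class:`ConvergenceTrace`.
    """
    config = config or FitConfig()
    if series.ndim != geometry.ndim:
        raise ValidationError("series and geometry dimensionality differ")
    n = config.n_integration_points
    taus = np.linspace(0.0, 1.0, n)
    times = series.times
    weights = series.sets[0].weights
    wsum = float(weights.sum())
    substeps = config.integration_substeps_per_slice_interval
    brackets = [_bracket(times, float(tau)) for tau in taus]

    lower, upper = geometry.lower, geometry.upper
    for k, s in enumerate(series.sets):
        outside = np.any((s.coords < lower) | (s.coords > upper), axis=1)
        if outside.any():
            logger.warning("point set %d: %d/%d points outside the domain "
                           "(clamped for field evaluation)", k,
                           int(outside.sum()), s.n_points)

    vdata = np.zeros((n,) + geometry.size + (geometry.ndim,), dtype=np.float32)
    avg_trace: list[float] = []
    uavg_trace: list[float] = []
    med_trace: list[list[float]] = []
    for iteration in range(config.max_iterations):
        v = VelocityField(geometry, vdata)
        errs, uerrs, meds = [], [], []
        for i, tau in enumerate(taus):
            a, b = brackets[i]
            ta, tb = float(times[a]), float(times[b])
            xa = _propagate(series.sets[a].coords, v, ta, float(tau), substeps)
            xb = _propagate(series.sets[b].coords, v, tb, float(tau), substeps)
            r = xb - xa
            if not np.all(np.isfinite(r)):
                raise NumericalError(
                    f"non-finite residuals at integration point {i} "
                    f"(iteration {iteration})")
            mid = 0.5 * (xa + xb)
            u = r / (tb - ta)
            norms = np.linalg.norm(r, axis=1)
            errs.append(float(np.sum(weights * norms) / wsum))
            uerrs.append(float(np.mean(norms)))
            meds.append(float(np.median(norms)))
            upd = fit_scattered_field(mid, u, weights, geometry, config.bspline)
            vdata[i] += config.step_size * upd.vectors
        avg_trace.append(float(np.mean(errs)))
        uavg_trace.append(float(np.mean(uerrs)))
        med_trace.append(meds)
        if _windowed_converged(avg_trace, config.convergence_tolerance):
            logger.info("converged after %d iterations", iteration + 1)
            break
    trace = ConvergenceTrace(np.asarray(avg_trace), np.asarray(med_trace),
                             np.asarray(uavg_trace))
    return VelocityField(geometry, vdata), trace


def _windowed_converged(avg: list[float], tol: float, window: int = 10) -> bool:
    # change of the `window`-iteration mean of the average error; strict <,
    # so the default tol = 0 always runs the full iteration budget
    if len(avg) < window + 1:
        return False
    cur = float(np.mean(avg[-window:]))
    prev = float(np.mean(avg[-window - 1:-1]))
    return abs(cur - prev) < tol
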