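"""Model/results interface over the velocity-flow fitting engine.

:class:`VelocityFlowModel` is constructed from a chronologically ordered
series of corresponding point sets and the geometry of the spatial domain;
``fit()`` runs the velocity-field optimization and returns a
:class:`VelocityFlowResults` carrying the fitted field, the convergence
trace and everything needed to transform points and images between arbitrary
times, build virtual templates, and persist/reload the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import __version__
from .field_core import (
    GridGeometry,
    PointSet,
    PointSetSeries,
    ValidationError,
    VelocityField,
    read_field,
    read_field_sidecar,
    read_point_set,
    sidecar_path,
    write_field,
)
from .temporal_mapping import TimeMap, normalize_time_points
from .velocity_flow import (
    ConvergenceTrace,
    FitConfig,
    fit_velocity_flow,
    integrate_velocity_field,
    transform_image_in_time,
    transform_points_in_time,
)

__all__ = ["VelocityFlowModel", "VelocityFlowResults"]


class VelocityFlowModel:
    """Time-varying velocity-field model of a corresponding point-set series.

    Parameters
    ----------
    series
        K >= 2 point sets in row-wise correspondence with strictly
        increasing normalized times spanning [0, 1].
    geometry
        The axis-aligned grid on which the velocity field is sampled.
    config
        Optimization parameters; defaults follow the reference workflow
        (N = 11 integration points, step size 0.2, 200 iterations).
    time_map
        Optional chronological-to-normalized time map, persisted with the
        fitted model so downstream use can address times in raw days.

    Examples
    --------
    >>> series, _ = generate_flow_series(spec, geometry)   # doctest: +SKIP
    >>> res = VelocityFlowModel(series, geometry).fit()    # doctest: +SKIP
    >>> moved = res.transform_points(series.sets[0], 0.0, 1.0)  # doctest: +SKIP
    """

    def __init__(self, series: PointSetSeries, geometry: GridGeometry,
                 config: FitConfig | None = None,
                 time_map: TimeMap | None = None):
        self.series = series
        self.geometry = geometry
        self.config = config or FitConfig()
        self.time_map = time_map

    @classmethod
    def from_point_set_files(cls, paths, raw_days, geometry: GridGeometry,
                             use_log: bool = True,
                             config: FitConfig | None = None,
                             ) -> "VelocityFlowModel":
        """Build a model from point-set CSV files tagged with raw days."""
        paths = list(paths)
        if len(paths) < 2:
            raise ValidationError("need at least two point-set files")
        if len(paths) != len(list(raw_days)):
            raise ValidationError("need one chronological day per file")
        tm = normalize_time_points(raw_days, use_log=use_log)
        sets = tuple(read_point_set(p) for p in paths)
        series = PointSetSeries(sets, np.asarray(tm.normalized))
        return cls(series, geometry, config=config, time_map=tm)

    def fit(self) -> "VelocityFlowResults":
        """Optimize the velocity field; deterministic given inputs/config."""
        field, trace = fit_velocity_flow(self.series, self.geometry,
                                         self.config)
        return VelocityFlowResults(self, field, trace)


@dataclass
class VelocityFlowResults:
    """Fitted velocity flow: field, diagnostics, and transform methods."""

    model: VelocityFlowModel
    velocity_field: VelocityField
    trace: ConvergenceTrace

    # -- transforms ---------------------------------------------------------

    @property
    def _substeps(self) -> int:
        return self.model.config.integration_substeps_per_slice_interval

    def displacement(self, t0: float, t1: float):
        """Dense displacement field mapping time t0 to time t1."""
        return integrate_velocity_field(self.velocity_field, t0, t1,
                                        substeps=self._substeps)

    def transform_points(self, points: PointSet, t0: float,
                         t1: float) -> PointSet:
        """Flow a point set from normalized time t0 to t1."""
        return transform_points_in_time(points, self.velocity_field, t0, t1,
                                        substeps=self._substeps)

    def transform_image(self, image: np.ndarray, t0: float, t1: float,
                        interpolation: str = "linear") -> np.ndarray:
        """Warp an image from time t0 into the space of time t1."""
        return transform_image_in_time(image, self.velocity_field, t0, t1,
                                       interpolation=interpolation,
                                       substeps=self._substeps)

    def virtual_template(self, images, times, target_time: float,
                         weighting: str = "temporal") -> np.ndarray:
        """Average temporally adjacent volumes warped to ``target_time``."""
        from .atlas_sampling import make_virtual_template

        return make_virtual_template(images, times, target_time,
                                     self.velocity_field, weighting=weighting,
                                     substeps=self._substeps)

    # -- diagnostics --------------------------------------------------------

    @property
    def final_error(self) -> float:
        return float(self.trace.average_error[-1])

    def summary(self) -> str:
        """Human-readable fit summary (configuration and error trace)."""
        cfg = self.model.config
        tr = self.trace
        lines = [
            "Velocity Flow Transformation Model",
            "=" * 50,
            f"point sets (K):            {self.model.series.n_sets}",
            f"points per set (M):        {self.model.series.n_points}",
            f"spatial dimensions (D):    {self.model.series.ndim}",
            f"grid size:                 {self.model.geometry.size}",
            f"grid spacing:              {self.model.geometry.spacing}",
            f"integration points (N):    {cfg.n_integration_points}",
            f"step size (delta):         {cfg.step_size}",
            f"iterations run:            {tr.n_iterations}"
            f" (budget {cfg.max_iterations})",
            f"initial avg displacement:  {tr.average_error[0]:.6g}",
            f"final avg displacement:    {tr.average_error[-1]:.6g}",
            "final median error/slice:  "
            + ", ".join(f"{e:.3g}" for e in tr.median_error[-1]),
        ]
        if self.model.time_map is not None:
            tm = self.model.time_map
            lines.append(f"chronological days:        {tm.raw_days} "
                         f"(log={tm.use_log})")
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Plot average and per-slice median displacement error curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        it = np.arange(self.trace.n_iterations)
        ax.plot(it, self.trace.average_error, "k-", lw=2,
                label="average error")
        for i in range(self.trace.median_error.shape[1]):
            ax.plot(it, self.trace.median_error[:, i], alpha=0.4, lw=0.8)
        ax.set_xlabel("iteration")
        ax.set_ylabel("displacement error")
        ax.legend()
        return ax

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write the model as velocity-field NIfTI + JSON sidecar (+trace CSV).

        The sidecar records the fit configuration, iterations run, the full
        convergence trace, package version and (if present) the raw-day time
        map, so any downstream command can reproduce the normalized times.
        """
        extra = {
            "step_size": self.model.config.step_size,
            "iterations_run": self.trace.n_iterations,
            "convergence_trace": self.trace.to_dict(),
            "fit_config": self.model.config.to_dict(),
            "velflow_version": __version__,
        }
        if self.model.time_map is not None:
            extra["time_map"] = self.model.time_map.to_dict()
        write_field(self.velocity_field, path, extra_sidecar=extra)
        trace_path = sidecar_path(path).with_suffix(".trace.csv")
        self.trace.to_dataframe().to_csv(trace_path, index=False)

    @classmethod
    def load(cls, path) -> "VelocityFlowResults":
        """Reload a saved model (series data is not stored, only the fit)."""
        field = read_field(path)
        if not isinstance(field, VelocityField):
            raise ValidationError(f"{path} does not hold a velocity field")
        meta = read_field_sidecar(path)
        cfg = FitConfig.from_dict(meta["fit_config"]) if "fit_config" in meta \
            else FitConfig(n_integration_points=field.n_slices)
        tm = TimeMap.from_dict(meta["time_map"]) if "time_map" in meta else None
        tr = meta.get("convergence_trace")
        trace = ConvergenceTrace(
            np.asarray(tr["average_error"]), np.asarray(tr["median_error"]),
            np.asarray(tr["unweighted_average_error"])) if tr else \
            ConvergenceTrace(np.zeros(1), np.zeros((1, field.n_slices)),
                             np.zeros(1))
        # reconstruct a minimal model shell: the series itself is not persisted
        shell = VelocityFlowModel.__new__(VelocityFlowModel)
        shell.series = None
        shell.geometry = field.geometry
        shell.config = cfg
        shell.time_map = tm
        return cls(shell, field, trace)
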