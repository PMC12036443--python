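"""Core data model: sampling grids, corresponding point sets, and the vector
fields (velocity and displacement) that live on those grids.

Conventions used throughout the package
---------------------------------------
* Coordinates are **physical** (e.g. micrometres), never voxel indices.
* Voxel *centers* define positions: the center of voxel ``i`` along axis
  ``a`` sits at ``origin[a] + i * spacing[a]``.  Indices are 0-based.
* Grids are axis-aligned; oblique direction matrices are rejected at load
  time.
* Vector fields are stored as 32-bit floats; one D-vector per voxel.
* Field evaluation outside the grid clamps the query to the domain boundary
  (zero-padding would create artificial velocity discontinuities at the edge
  during trajectory integration).

A :class:`VelocityField` holds N time-slices attached to the uniformly
spaced integration times ``tau_i = i / (N - 1)`` in normalized time [0, 1];
each voxel of slice ``i`` stores the velocity in physical units per unit
normalized time.  A :class:`DisplacementField` is a single spatial vector
field mapping each voxel center to an offset.
"""

from __future__ import annotations

import itertools
import json
import pathlib
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GridGeometry",
    "PointSet",
    "PointSetSeries",
    "VelocityField",
    "DisplacementField",
    "interpolate_vector_field",
    "read_point_set",
    "write_point_set",
    "read_field",
    "write_field",
]

NIFTI_INTENT_VECTOR = 1007


class ValidationError(ValueError):
    """An input violated a structural invariant of the data model."""


# ---------------------------------------------------------------------------
# grid geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridGeometry:
    """Physical description of an axis-aligned sampling lattice.

    Parameters
    ----------
    size
        Voxel count per spatial axis (D = 2 or 3 axes, each >= 2).
    spacing
        Physical length per voxel per axis (all > 0, one unit throughout).
    origin
        Physical coordinate of the *center* of the first voxel per axis.
    """

    size: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...]

    def __post_init__(self):
        size = tuple(int(s) for s in self.size)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "size", size)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        if len(size) not in (2, 3):
            raise ValidationError(f"grid must be 2-D or 3-D, got {len(size)} axes")
        if not (len(size) == len(spacing) == len(origin)):
            raise ValidationError("size, spacing and origin must have equal length")
        if any(s < 2 for s in size):
            raise ValidationError(f"all grid sizes must be >= 2, got {size}")
        if any(s <= 0 for s in spacing):
            raise ValidationError(f"all spacings must be > 0, got {spacing}")
        if not all(np.isfinite(spacing)) or not all(np.isfinite(origin)):
            raise ValidationError("spacing and origin must be finite")

    @property
    def ndim(self) -> int:
        return len(self.size)

    @property
    def lower(self) -> np.ndarray:
        """Physical coordinate of the first voxel center."""
        return np.asarray(self.origin, dtype=float)

    @property
    def upper(self) -> np.ndarray:
        """Physical coordinate of the last voxel center."""
        return self.lower + (np.asarray(self.size) - 1) * np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates of all voxel centers, shape ``(*size, D)``."""
        axes = [
            self.origin[a] + np.arange(self.size[a]) * self.spacing[a]
            for a in range(self.ndim)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    def continuous_index(self, coords: np.ndarray) -> np.ndarray:
        """Map physical coordinates to (fractional) voxel indices."""
        coords = np.asarray(coords, dtype=float)
        return (coords - self.lower) / np.asarray(self.spacing)

    def to_dict(self) -> dict:
        return {"size": list(self.size), "spacing": list(self.spacing),
                "origin": list(self.origin)}

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(tuple(d["size"]), tuple(d["spacing"]), tuple(d["origin"]))


# ---------------------------------------------------------------------------
# point sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PointSet:
    """M physical points with per-point weights and stable identifiers.

    Correspondence across point sets is positional: row ``j`` in every set of
    a series refers to the same anatomical sample.
    """

    coords: np.ndarray  # (M, D) float64
    ids: tuple[str, ...] = None
    weights: np.ndarray = None

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "coords", coords)
        m = coords.shape[0]
        if m < 1 or coords.ndim != 2:
            raise ValidationError("coords must be a non-empty (M, D) array")
        if coords.shape[1] not in (2, 3):
            raise ValidationError(f"points must be 2-D or 3-D, got D={coords.shape[1]}")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("point coordinates must be finite")
        ids = self.ids
        if ids is None:
            ids = tuple(f"p{j:06d}" for j in range(m))
        else:
            ids = tuple(str(i) for i in ids)
        object.__setattr__(self, "ids", ids)
        if len(ids) != m:
            raise ValidationError("number of ids must match number of points")
        if len(set(ids)) != m:
            seen: set[str] = set()
            dups = [i for i in ids if i in seen or seen.add(i)]
            raise ValidationError(f"duplicate point ids: {sorted(set(dups))[:5]}")
        w = self.weights
        w = np.ones(m) if w is None else np.asarray(w, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (m,) or not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValidationError("weights must be M finite positive values")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray) -> "PointSet":
        """Same ids/weights, new coordinates (used by point transforms)."""
        return PointSet(coords, ids=self.ids, weights=self.weights)


@dataclass(frozen=True)
class PointSetSeries:
    """K corresponding point sets tagged with normalized times in [0, 1].

    All sets must share M, D, ids and weights; times are strictly increasing
    with ``times[0] == 0`` and ``times[-1] == 1``.
    """

    sets: tuple[PointSet, ...]
    times: np.ndarray

    def __post_init__(self):
        sets = tuple(self.sets)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "sets", sets)
        object.__setattr__(self, "times", times)
        if len(sets) < 2:
            raise ValidationError("a series needs K >= 2 point sets")
        if times.shape != (len(sets),):
            raise ValidationError("one time per point set is required")
        if not (np.all(np.diff(times) > 0) and times[0] == 0.0 and times[-1] == 1.0):
            raise ValidationError(
                "times must be strictly increasing with times[0]=0, times[-1]=1")
        ref = sets[0]
        for k, s in enumerate(sets[1:], start=1):
            if s.coords.shape != ref.coords.shape:
                raise ValidationError(f"set {k} shape differs from set 0")
            if s.ids != ref.ids:
                raise ValidationError(f"set {k} ids differ from set 0")
            if not np.array_equal(s.weights, ref.weights):
                raise ValidationError(f"set {k} weights differ from set 0")

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_points(self) -> int:
        return self.sets[0].n_points

    @property
    def ndim(self) -> int:
        return self.sets[0].ndim


# ---------------------------------------------------------------------------
# vector fields
# ---------------------------------------------------------------------------


def _as_field_array(values, geometry: GridGeometry, extra_leading: bool) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float32)
    expected = geometry.size + (geometry.ndim,)
    if extra_leading:
        if arr.ndim != len(expected) + 1 or arr.shape[1:] != expected:
            raise ValidationError(
                f"velocity data must have shape (N, {expected}), got {arr.shape}")
        if arr.shape[0] < 2:
            raise ValidationError("a velocity field needs N >= 2 time slices")
    elif arr.shape != expected:
        raise ValidationError(
            f"field shape {arr.shape} does not match geometry {expected}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("field values must be finite")
    return arr


@dataclass(frozen=True)
class DisplacementField:
    """A spatial vector field: one physical D-vector per voxel center."""

    geometry: GridGeometry
    vectors: np.ndarray  # (*size, D) float32

    def __post_init__(self):
        object.__setattr__(
            self, "vectors", _as_field_array(self.vectors, self.geometry, False))

    @classmethod
    def zeros(cls, geometry: GridGeometry) -> "DisplacementField":
        return cls(geometry, np.zeros(geometry.size + (geometry.ndim,), np.float32))


@dataclass(frozen=True)
class VelocityField:
    """N spatial vector-field slices spanning normalized time [0, 1].

    Slice ``i`` is attached to the integration time ``tau_i = i / (N - 1)``;
    voxel values are velocities in physical units per unit normalized time.
    """

    geometry: GridGeometry
    data: np.ndarray  # (N, *size, D) float32

    def __post_init__(self):
        object.__setattr__(
            self, "data", _as_field_array(self.data, self.geometry, True))

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_slices)

    def slice(self, i: int) -> DisplacementField:
        """Slice ``i`` viewed as a static vector field."""
        return DisplacementField(self.geometry, self.data[i])

    @classmethod
    def zeros(cls, geometry: GridGeometry, n_slices: int) -> "VelocityField":
        return cls(geometry,
                   np.zeros((n_slices,) + geometry.size + (geometry.ndim,),
                            np.float32))


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


def interpolate_values(values: np.ndarray, geometry: GridGeometry,
                       queries: np.ndarray) -> np.ndarray:
    """Multilinear interpolation of per-voxel vectors at physical queries.

    Queries outside the domain are clamped to the nearest boundary position.
    ``values`` has shape ``(*size, C)``; returns ``(Q, C)``.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if not np.all(np.isfinite(queries)):
        raise ValidationError("interpolation queries must be finite")
    d = geometry.ndim
    if queries.shape[1] != d:
        raise ValidationError(f"queries must be (Q, {d})")
    size = np.asarray(geometry.size)
    u = np.clip(geometry.continuous_index(queries), 0.0, size - 1)
    i0 = np.minimum(np.floor(u).astype(int), size - 2)
    f = u - i0
    out = np.zeros((queries.shape[0], values.shape[-1]))
    for corner in itertools.product((0, 1), repeat=d):
        w = np.ones(queries.shape[0])
        for a, c in enumerate(corner):
            w = w * (f[:, a] if c else 1.0 - f[:, a])
        idx = tuple(i0[:, a] + corner[a] for a in range(d))
        out += w[:, None] * values[idx]
    return out


def interpolate_vector_field(field: DisplacementField,
                             queries: np.ndarray) -> np.ndarray:
    """Evaluate a vector field at physical coordinates (clamped multilinear)."""
    return interpolate_values(field.vectors, field.geometry, queries)


# ---------------------------------------------------------------------------
# point-set I/O (CSV, header id,x,y[,z][,weight])
# ---------------------------------------------------------------------------


def write_point_set(points: PointSet, path) -> None:
    """Write a point set as CSV with header ``id,x,y[,z],weight``."""
    cols = ["x", "y", "z"][: points.ndim]
    df = pd.DataFrame({"id": list(points.ids)})
    for a, c in enumerate(cols):
        df[c] = points.coords[:, a]
    df["weight"] = points.weights
    df.to_csv(path, index=False)


def read_point_set(path) -> PointSet:
    """Read a point set from CSV.

    The header must be ``id,x,y[,z][,weight]``; a missing weight column
    implies unit weights.  Duplicate ids or non-numeric coordinates raise a
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "id" not in cols or "x" not in cols or "y" not in cols:
        raise ValidationError(f"{path}: header must contain id,x,y[,z][,weight]")
    coord_cols = ["x", "y", "z"] if "z" in cols else ["x", "y"]
    data = []
    for c in coord_cols + (["weight"] if "weight" in cols else []):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-numeric value {df[c].iloc[row]!r} in column "
                f"{c!r} at data row {row}")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValidationError(f"{path}: missing value in column {c!r} at "
                                  f"data row {row}")
        data.append(vals.to_numpy(dtype=float))
    ids = df["id"].tolist()
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        row = int(dup.index[0])
        raise ValidationError(f"{path}: duplicate id {dup.iloc[0]!r} at data "
                              f"row {row}")
    coords = np.column_stack(data[: len(coord_cols)])
    weights = data[len(coord_cols)] if "weight" in cols else None
    return PointSet(coords, ids=tuple(ids), weights=weights)


# ---------------------------------------------------------------------------
# field I/O (NIfTI-1 + JSON sidecar)
# ---------------------------------------------------------------------------
#
# Displacement field: dims [nx, ny, nz, 1, D], vector components on the 5th
# axis with the "vector" intent code -- the layout ANTs-style tools emit.
# Velocity field: dims [nx, ny, nz, N, D] plus a JSON sidecar carrying the
# number of integration points, normalized times and the fit configuration.
# 2-D fields are stored with nz = 1.


def sidecar_path(path) -> pathlib.Path:
    p = pathlib.Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return p.with_name(name + ".json")


def _affine_from_geometry(geometry: GridGeometry) -> np.ndarray:
    aff = np.eye(4)
    for a in range(geometry.ndim):
        aff[a, a] = geometry.spacing[a]
        aff[a, 3] = geometry.origin[a]
    return aff


def _geometry_from_img(img, d: int, spatial_shape) -> GridGeometry:
    aff = img.affine
    off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if np.max(np.abs(off)) > 1e-6 * max(1.0, np.max(np.abs(aff[:3, :3]))):
        raise ValidationError(
            "only axis-aligned (diagonal, positive) direction matrices are "
            "supported; reorient the image first")
    diag = np.diag(aff[:3, :3])[:d]
    if np.any(diag <= 0):
        raise ValidationError("negative or zero voxel spacing in affine; "
                              "only identity directions are supported")
    return GridGeometry(tuple(int(s) for s in spatial_shape[:d]),
                        tuple(float(s) for s in diag),
                        tuple(float(o) for o in aff[:d, 3]))


def write_field(fld, path, extra_sidecar: dict | None = None) -> None:
    """Write a displacement or velocity field as NIfTI-1 (+ JSON sidecar)."""
    geom = fld.geometry
    d = geom.ndim
    if isinstance(fld, VelocityField):
        n = fld.n_slices
        arr = np.moveaxis(fld.data, 0, -2)  # (*size, N, D)
    else:
        n = 1
        arr = fld.vectors[..., None, :]  # (*size, 1, D)
    if d == 2:
        arr = arr[:, :, None, ...]  # insert nz = 1
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32),
                          _affine_from_geometry(geom))
    img.header.set_intent(NIFTI_INTENT_VECTOR)
    zooms = list(geom.spacing) + [1.0] * (5 - d)
    img.header.set_zooms(tuple(zooms[: len(img.shape)]))
    nib.save(img, str(path))
    if isinstance(fld, VelocityField):
        meta = {
            "n_integration_points": n,
            "times_normalized": [float(t) for t in fld.times],
            "geometry": geom.to_dict(),
        }
        if extra_sidecar:
            meta.update(extra_sidecar)
        sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_field(path):
    """Read a field written by :func:`write_field`.

    Returns a :class:`DisplacementField` when the 4th axis has length 1 and
    no sidecar is present, otherwise a :class:`VelocityField` (sidecar
    required, and its recorded N must match the 4th-axis length).
    """
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) != 5:
        raise ValidationError(f"{path}: expected a 5-D vector NIfTI, got "
                              f"shape {shape}")
    d = shape[4]
    if d not in (2, 3):
        raise ValidationError(f"{path}: vector dimension must be 2 or 3")
    n = shape[3]
    geom = _geometry_from_img(img, d, shape[:3])
    arr = np.asanyarray(img.dataobj, dtype=np.float32)
    if d == 2:
        if shape[2] != 1:
            raise ValidationError(f"{path}: 2-D field must have nz = 1")
        arr = arr[:, :, 0, ...]
    sc = sidecar_path(path)
    if n == 1 and not sc.exists():
        return DisplacementField(geom, arr[..., 0, :])
    if not sc.exists():
        raise ValidationError(
            f"{path}: velocity field requires the JSON sidecar {sc.name}")
    meta = json.loads(sc.read_text())
    if int(meta.get("n_integration_points", -1)) != n:
        raise ValidationError(
            f"{path}: sidecar n_integration_points="
            f"{meta.get('n_integration_points')} disagrees with 4th-axis "
            f"length {n}")
    if "geometry" in meta:
        side_geom = GridGeometry.from_dict(meta["geometry"])
        if side_geom != geom:
            raise ValidationError(f"{path}: sidecar geometry disagrees with "
                                  "the NIfTI header")
    return VelocityField(geom, np.moveaxis(arr, -2, 0))


def read_field_sidecar(path) -> dict:
    """Return the sidecar metadata for a field file (empty dict if absent)."""
    sc = sidecar_path(path)
    return json.loads(sc.read_text()) if sc.exists() else {}
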