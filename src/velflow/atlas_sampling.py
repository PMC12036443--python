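"""Point-set construction from multi-label volumes and virtual templates.

The fitting input for an atlas series is built once in a reference stage:
label boundaries and region interiors are subsampled into a weighted point
set, then propagated through externally supplied stage-to-stage displacement
fields to obtain the corresponding sets at every other stage.  Boundary
points carry a higher confidence weight than interior points so the smooth
update fields respect region outlines.

Defaults mirror the reference workflow: 10% of boundary voxels, 1% of
interior voxels, boundary weight twice the interior weight.  Sampling is
stratified per label, without replacement, and deterministic given the seed.

Virtual templates at an intermediate time are built by warping temporally
adjacent intensity volumes to the target time through the fitted velocity
field and averaging voxelwise (uniformly or with inverse-temporal-distance
weights); no registration-based shape refinement is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_core import (
    DisplacementField,
    GridGeometry,
    PointSet,
    ValidationError,
    VelocityField,
    interpolate_vector_field,
)
from .velocity_flow import transform_image_in_time

__all__ = [
    "LabelVolume",
    "SamplingConfig",
    "sample_label_points",
    "boundary_mask",
    "propagate_points",
    "centroid_translation",
    "make_virtual_template",
]


@dataclass(frozen=True)
class LabelVolume:
    """Integer label image on a grid; label 0 is background."""

    geometry: GridGeometry
    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("labels must be integers")
            arr = np.round(arr).astype(np.int32)
        if tuple(arr.shape) != self.geometry.size:
            raise ValidationError(
                f"label shape {arr.shape} does not match geometry "
                f"{self.geometry.size}")
        if np.any(arr < 0):
            raise ValidationError("labels must be non-negative")
        object.__setattr__(self, "labels", arr)


@dataclass(frozen=True)
class SamplingConfig:
    """Label sampling rates, weights and RNG seed.

    ``contour_rate`` / ``region_rate`` are the fractions of boundary and
    interior voxels retained per label (a rate of 0 skips the stratum);
    boundary points receive ``boundary_weight``, interior points
    ``interior_weight``.
    """

    contour_rate: float = 0.10
    region_rate: float = 0.01
    boundary_weight: float = 2.0
    interior_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("contour_rate", "region_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.boundary_weight <= 0 or self.interior_weight <= 0:
            raise ValidationError("weights must be > 0")

    def to_dict(self) -> dict:
        return {"contour_rate": self.contour_rate,
                "region_rate": self.region_rate,
                "boundary_weight": self.boundary_weight,
                "interior_weight": self.interior_weight, "seed": self.seed}


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels with a face-adjacent neighbour of a different label.

    Face adjacency (6-connectivity in 3-D, 4 in 2-D); background (0) counts
    as a different label, and so does the outside of the volume.
    """
    labels = np.asarray(labels)
    mask = np.zeros(labels.shape, dtype=bool)
    for axis in range(labels.ndim):
        lo = [slice(None)] * labels.ndim
        hi = [slice(None)] * labels.ndim
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        diff = labels[tuple(lo)] != labels[tuple(hi)]
        mask[tuple(lo)] |= diff
        mask[tuple(hi)] |= diff
        edge = [slice(None)] * labels.ndim
        edge[axis] = 0
        mask[tuple(edge)] = True
        edge[axis] = -1
        mask[tuple(edge)] = True
    return mask


def _stratum_count(rate: float, n: int) -> int:
    if rate == 0.0 or n == 0:
        return 0
    return max(1, int(np.floor(rate * n + 0.5)))


def sample_label_points(volume: LabelVolume, config: SamplingConfig,
                        ) -> tuple[PointSet, dict]:
    """Stratified per-label sampling of boundary and interior voxels.

    For every non-background label, boundary voxels are sampled without
    replacement at ``contour_rate`` and the remaining interior voxels at
    ``region_rate`` (``round(rate * count)`` samples, at least one when the
    stratum is non-empty and the rate positive).  Point coordinates are voxel
    centers in physical space; ids encode label, stratum and index.

    Returns the point set and a manifest of per-label counts.
    """
    labels = volume.labels
    present = np.unique(labels)
    present = present[present > 0]
    if present.size == 0:
        raise ValidationError("label volume has no non-background voxels")
    rng = np.random.default_rng(config.seed)
    bmask = boundary_mask(labels)
    spacing = np.asarray(volume.geometry.spacing)
    origin = np.asarray(volume.geometry.origin)

    coords, weights, ids = [], [], []
    manifest: dict = {"seed": config.seed,
                      "contour_rate": config.contour_rate,
                      "region_rate": config.region_rate, "labels": {}}
    for label in present:
        inside = labels == label
        strata = (("boundary", inside & bmask, config.contour_rate,
                   config.boundary_weight),
                  ("interior", inside & ~bmask, config.region_rate,
                   config.interior_weight))
        entry = {}
        for name, mask, rate, weight in strata:
            voxels = np.argwhere(mask)
            k = _stratum_count(rate, voxels.shape[0])
            entry[name] = {"available": int(voxels.shape[0]), "sampled": k}
            if k == 0:
                continue
            chosen = voxels[rng.choice(voxels.shape[0], size=k, replace=False)]
            coords.append(origin + chosen * spacing)
            weights.append(np.full(k, weight))
            ids.extend(f"L{int(label)}:{name}:{j}" for j in range(k))
        manifest["labels"][int(label)] = entry
    if not coords:
        raise ValidationError("sampling rates selected no voxels")
    points = PointSet(np.concatenate(coords), ids=tuple(ids),
                      weights=np.concatenate(weights))
    return points, manifest


def propagate_points(points: PointSet,
                     transforms: list[DisplacementField]) -> PointSet:
    """Push a point set through an ordered chain of displacement fields.

    Each field's value is interpolated at the current position and added;
    ids and weights are preserved.  This constructs the cross-stage
    correspondence the flow fit consumes from externally produced pairwise
    registrations.
    """
    coords = np.array(points.coords, dtype=float, copy=True)
    for fld in transforms:
        coords = coords + interpolate_vector_field(fld, coords)
    return points.with_coords(coords)


def centroid_translation(fixed: LabelVolume, moving: LabelVolume) -> np.ndarray:
    """Translation aligning the shared-label centroids of two label volumes.

    Rigid pre-normalization reduced to its translational part: the mean over
    shared non-background labels of (fixed centroid - moving centroid).  Add
    the result to ``moving``-space coordinates before propagation.
    """
    shared = np.intersect1d(np.unique(fixed.labels), np.unique(moving.labels))
    shared = shared[shared > 0]
    if shared.size == 0:
        raise ValidationError("volumes share no non-background labels")

    def centroid(vol: LabelVolume, label) -> np.ndarray:
        idx = np.argwhere(vol.labels == label).mean(axis=0)
        return np.asarray(vol.geometry.origin) + idx * np.asarray(
            vol.geometry.spacing)

    diffs = [centroid(fixed, lb) - centroid(moving, lb) for lb in shared]
    return np.mean(diffs, axis=0)


def make_virtual_template(images, times, target_time: float,
                          v: VelocityField, weighting: str = "temporal",
                          substeps: int = 4) -> np.ndarray:
    """Synthesize an intensity volume at a time absent from the series.

    Every input image is warped from its own normalized time to
    ``target_time`` through the velocity field and the warps are combined
    voxelwise: ``weighting="uniform"`` averages equally,
    ``weighting="temporal"`` weights each image proportionally to
    ``1 / |t_image - target_time|`` (normalized to sum 1), short-circuiting
    to an exact copy when an input sits at the target time.
    """
    images = [np.asarray(img, dtype=float) for img in images]
    times = [float(t) for t in times]
    if len(images) == 0 or len(images) != len(times):
        raise ValidationError("need equally many images and times")
    if not (0.0 <= target_time <= 1.0):
        raise ValidationError(f"target time {target_time} outside [0, 1]")
    if weighting not in ("uniform", "temporal"):
        raise ValidationError("weighting must be 'uniform' or 'temporal'")
    for img in images:
        if img.shape != v.geometry.size:
            raise ValidationError("all images must live on the field geometry")
    if weighting == "temporal":
        for img, t in zip(images, times):
            if abs(t - target_time) < 1e-12:
                return img.copy()
        w = np.array([1.0 / abs(t - target_time) for t in times])
    else:
        w = np.ones(len(images))
    w = w / w.sum()
    out = np.zeros(v.geometry.size)
    for img, t, wi in zip(images, times, w):
        out += wi * transform_image_in_time(img, v, t, target_time,
                                            substeps=substeps)
    return out
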