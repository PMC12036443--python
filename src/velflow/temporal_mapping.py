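"""Chronological-age to normalized-time conversion.

Developmental atlas series sample ages very unevenly (embryonic stages days
apart, postnatal stages weeks apart).  Fitting in raw days would concentrate
the velocity field's integration points in the long postnatal gaps, so ages
are log-transformed before min-max normalization to the [0, 1] fitting
domain: equal *ratios* of age then map to equal normalized gaps, which
spreads the samples far more evenly along the trajectory.

For the seven-stage developmental mouse series (E11.5 ... P56) the package
places postnatal day d at ``EMBRYONIC_TERM_DAYS + d`` continuous days (birth
at E18.5/P0), and caps the last stage at 28 postnatal days -- by P28 the
brain's growth has essentially plateaued, so P56 is temporally equivalent.
The offset is a named constant and fully overridable: only the 28-day cap is
an established convention, the concatenation offset is a documented package
choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_core import ValidationError

__all__ = [
    "TimeMap",
    "normalize_time_points",
    "denormalize_time",
    "devccf_default_days",
    "EMBRYONIC_TERM_DAYS",
    "DEVCCF_STAGE_NAMES",
]

# continuous age (days post conception) assigned to birth: postnatal day d
# sits at EMBRYONIC_TERM_DAYS + d
EMBRYONIC_TERM_DAYS = 18.5

# effective postnatal age used for the oldest stage (P56): growth plateaus,
# so 28 days is used in its place
P56_EFFECTIVE_POSTNATAL_DAYS = 28.0

DEVCCF_STAGE_NAMES = ("E11.5", "E13.5", "E15.5", "E18.5", "P4", "P14", "P56")


@dataclass(frozen=True)
class TimeMap:
    """Monotone map between raw chronological days and normalized [0, 1]."""

    raw_days: tuple[float, ...]
    use_log: bool
    normalized: tuple[float, ...]

    def normalize(self, day: float) -> float:
        """Normalized time of an arbitrary chronological day."""
        day = float(day)
        s = np.log(day) if self.use_log else day
        lo = np.log(self.raw_days[0]) if self.use_log else self.raw_days[0]
        hi = np.log(self.raw_days[-1]) if self.use_log else self.raw_days[-1]
        if self.use_log and day <= 0:
            raise ValidationError("chronological day must be > 0 in log mode")
        return float((s - lo) / (hi - lo))

    def to_dict(self) -> dict:
        return {"raw_days": list(self.raw_days), "use_log": self.use_log,
                "normalized": list(self.normalized)}

    @classmethod
    def from_dict(cls, d: dict) -> "TimeMap":
        return cls(tuple(d["raw_days"]), bool(d["use_log"]),
                   tuple(d["normalized"]))


def normalize_time_points(raw_days, use_log: bool = True) -> TimeMap:
    """Map strictly increasing chronological days onto normalized [0, 1].

    With ``use_log`` (the default) days are log-transformed first, so the
    geometric mean of the endpoints lands at 0.5 and ratios of days map to
    differences of normalized time.  Endpoints map to exactly 0 and 1.
    """
    raw = np.asarray(raw_days, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValidationError("need at least two chronological time points")
    if not np.all(np.diff(raw) > 0):
        raise ValidationError("chronological days must be strictly increasing")
    if use_log and np.any(raw <= 0):
        raise ValidationError("log-mode time points must all be > 0")
    s = np.log(raw) if use_log else raw
    norm = (s - s[0]) / (s[-1] - s[0])
    norm[0], norm[-1] = 0.0, 1.0
    return TimeMap(tuple(float(r) for r in raw), bool(use_log),
                   tuple(float(t) for t in norm))


def denormalize_time(t_normalized: float, time_map: TimeMap) -> float:
    """Exact inverse of :func:`normalize_time_points` for any t in [0, 1]."""
    t = float(t_normalized)
    if not (0.0 <= t <= 1.0):
        raise ValidationError(f"normalized time {t} outside [0, 1]")
    lo, hi = time_map.raw_days[0], time_map.raw_days[-1]
    if t == 0.0:
        return float(lo)
    if t == 1.0:
        return float(hi)
    if time_map.use_log:
        return float(np.exp(np.log(lo) + t * (np.log(hi) - np.log(lo))))
    return float(lo + t * (hi - lo))


def devccf_default_days() -> tuple[float, ...]:
    """Chronological days for the seven developmental stages E11.5 ... P56.

    Embryonic stages keep their E-day values; postnatal day d is placed at
    ``EMBRYONIC_TERM_DAYS + d`` with P56 replaced by its 28-day effective
    age, giving (11.5, 13.5, 15.5, 18.5, 22.5, 32.5, 46.5).
    """
    embryonic = (11.5, 13.5, 15.5, 18.5)
    postnatal = (4.0, 14.0, P56_EFFECTIVE_POSTNATAL_DAYS)
    return embryonic + tuple(EMBRYONIC_TERM_DAYS + d for d in postnatal)
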