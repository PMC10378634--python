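"""Daily 6-DOF setup errors: representation, sampling and rigid transforms.

Rotation convention: intrinsic rotations about the plan isocenter applied in
the order yaw (about z), pitch (about x), roll (about y); angles in degrees
in all I/O.  Translations are in mm along (x, y, z) = (left-right,
anterior-posterior, superior-inferior).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import ValidationError

__all__ = [
    "AXES",
    "FractionShift",
    "ShiftDistribution",
    "sample_fraction_shifts",
    "shift_magnitude",
    "rotation_matrix",
    "transform_points",
]

#: canonical axis order used in CSV logs and distribution parameters
AXES = ("tx", "ty", "tz", "yaw", "roll", "pitch")


@dataclass(frozen=True)
class FractionShift:
    """One fraction's rigid setup error (translations mm, rotations degrees)."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    yaw: float = 0.0
    roll: float = 0.0
    pitch: float = 0.0

    def __post_init__(self):
        vals = [self.tx, self.ty, self.tz, self.yaw, self.roll, self.pitch]
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"shift components must be finite, got {vals}")
        for name in ("yaw", "roll", "pitch"):
            a = getattr(self, name)
            if not (-180.0 < a <= 180.0):
                raise ValidationError(f"{name} must lie in (-180, 180], got {a}")

    @classmethod
    def zero(cls) -> "FractionShift":
        return cls()

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    @property
    def is_identity(self) -> bool:
        return all(
            getattr(self, a) == 0.0 for a in AXES
        )

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, a) for a in AXES)


@dataclass(frozen=True)
class ShiftDistribution:
    """Independent per-axis Gaussian model of daily setup errors.

    ``sd`` / ``mean`` follow the :data:`AXES` order: (tx, ty, tz, yaw, roll,
    pitch) with mm for translations and degrees for rotations.
    """

    sd: tuple[float, float, float, float, float, float]
    mean: tuple[float, float, float, float, float, float] = (0.0,) * 6
    seed: int | None = None

    def __post_init__(self):
        sd = tuple(float(s) for s in self.sd)
        mean = tuple(float(m) for m in self.mean)
        if len(sd) != 6 or len(mean) != 6:
            raise ValidationError("sd and mean must have 6 entries (tx,ty,tz,yaw,roll,pitch)")
        if any(s < 0 for s in sd):
            raise ValidationError(f"standard deviations must be >= 0, got {sd}")
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "mean", mean)


def sample_fraction_shifts(
    n: int,
    dist: ShiftDistribution,
    rng: np.random.Generator | None = None,
) -> list[FractionShift]:
    """Draw ``n`` independent per-axis Gaussian setup errors.

    Reproducible: if ``rng`` is not supplied, a fresh generator is seeded
    from ``dist.seed``.
    """
    if n < 1:
        raise ValidationError(f"fraction count must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(dist.seed)
    draws = rng.normal(loc=dist.mean, scale=dist.sd, size=(int(n), 6))
    return [FractionShift(*row) for row in draws]


def shift_magnitude(shift: FractionShift) -> float:
    """Euclidean norm of the translation part, in mm.

    Rotations are excluded: mixing degrees and mm in one norm is
    dimensionally unsound.
    """
    return float(np.linalg.norm(shift.translation))


def rotation_matrix(yaw_deg: float, pitch_deg: float, roll_deg: float) -> np.ndarray:
    """Rotation matrix for intrinsic yaw (z), pitch (x), roll (y), degrees."""
    cy, sy = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
    cp, sp = np.cos(np.radians(pitch_deg)), np.sin(np.radians(pitch_deg))
    cr, sr = np.cos(np.radians(roll_deg)), np.sin(np.radians(roll_deg))
    rz = np.array([[cy, -sy, 0.0], [sy, cy, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cp, -sp], [0.0, sp, cp]])
    ry = np.array([[cr, 0.0, sr], [0.0, 1.0, 0.0], [-sr, 0.0, cr]])
    return rz @ rx @ ry


def transform_points(
    points: np.ndarray,
    shift: FractionShift,
    isocenter: np.ndarray,
) -> np.ndarray:
    """Apply the rigid anatomy transform to an (N, 3) point array.

    Points rotate about ``isocenter`` and then translate; beams stay fixed,
    so evaluating the static beam model at the transformed points yields the
    dose the shifted anatomy receives.
    """
    points = np.asarray(points, dtype=float)
    iso = np.asarray(isocenter, dtype=float)
    if shift.is_identity:
        return points
    rot = rotation_matrix(shift.yaw, shift.pitch, shift.roll)
    return (points - iso) @ rot.T + iso + shift.translation
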