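"""Analytic proton-like dose model.

Each beam contributes ``weight * L(r_perp) * Z(depth)`` where ``L`` is a
Gaussian in the perpendicular distance to the beam axis and ``Z`` is a 1-D
depth profile: a linear proximal ramp, a plateau of height exactly 1 over
the modulated region, and a logistic distal falloff anchored at the
effective range ``nominal_range_mm * range_scale``.  The beam isocenter
sits mid-plateau, i.e. at depth ``R - M/2``.

This is deliberately simple — no heterogeneity, scatter or nuclear halo —
but it has the one property that matters here: a sharp distal edge whose
position responds to range scaling and whose lateral penumbra responds to
rigid setup errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from ..errors import NormalizationError, ValidationError
from .phantom import Phantom, Structure
from .shifts import FractionShift, transform_points

__all__ = [
    "PROXIMAL_FLOOR",
    "BeamSpec",
    "NormalizedPlan",
    "depth_dose",
    "beam_dose_at_points",
    "dose_at_points",
    "compute_dose",
    "normalize_plan",
    "calibrate_plan",
]

#: entrance dose as a fraction of plateau dose (start of the proximal ramp)
PROXIMAL_FLOOR = 0.7

_RANGE_SCALE_LIMITS = (0.8, 1.2)


@dataclass(frozen=True)
class BeamSpec:
    """Geometry and shape parameters of one analytic beam.

    ``target`` optionally names the structure the beam paints; plan
    calibration uses it to scale secondary-target fields independently.
    """

    direction: tuple[float, float, float]
    isocenter: tuple[float, float, float]
    nominal_range_mm: float
    modulation_mm: float
    lateral_sigma_mm: float
    falloff_sigma_mm: float
    weight: float = 1.0
    target: str | None = None

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValidationError(
                f"beam direction must be a unit 3-vector (|d|=1 within 1e-9), got {self.direction}"
            )
        if not self.nominal_range_mm > self.modulation_mm >= 0:
            raise ValidationError(
                f"need nominal_range_mm > modulation_mm >= 0, got "
                f"R={self.nominal_range_mm}, M={self.modulation_mm}"
            )
        if self.lateral_sigma_mm <= 0 or self.falloff_sigma_mm <= 0:
            raise ValidationError("beam sigmas must be > 0")
        if self.weight < 0:
            raise ValidationError(f"beam weight must be >= 0, got {self.weight}")
        object.__setattr__(self, "direction", tuple(float(v) for v in d))
        object.__setattr__(self, "isocenter", tuple(float(v) for v in self.isocenter))


def depth_dose(
    depth_mm: np.ndarray,
    nominal_range_mm: float,
    modulation_mm: float,
    falloff_sigma_mm: float,
    range_scale: float = 1.0,
) -> np.ndarray:
    """Normalized depth profile Z(d).

    Exactly 1 on the plateau ``[R_eff - M, R_eff]`` (R_eff = R * range_scale),
    linear ramp from :data:`PROXIMAL_FLOOR` at the surface, and the distal
    logistic ``2 / (1 + exp((d - R_eff) / sigma))`` beyond the plateau — the
    50% falloff depth is ``R_eff + sigma * ln 3``.
    """
    d = np.asarray(depth_mm, dtype=float)
    r_eff = nominal_range_mm * range_scale
    plateau_start = max(r_eff - modulation_mm, 0.0)
    z = np.zeros_like(d)
    if plateau_start > 0:
        prox = (d > 0) & (d < plateau_start)
        z[prox] = PROXIMAL_FLOOR + (1.0 - PROXIMAL_FLOOR) * d[prox] / plateau_start
    plateau = (d >= plateau_start) & (d <= r_eff)
    z[plateau] = 1.0
    distal = d > r_eff
    z[distal] = 2.0 / (1.0 + np.exp((d[distal] - r_eff) / falloff_sigma_mm))
    return z


def beam_dose_at_points(
    points: np.ndarray, beam: BeamSpec, range_scale: float = 1.0
) -> np.ndarray:
    """Dose from a single beam at fixed (room-frame) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if beam.weight == 0.0:
        return np.zeros(len(pts))
    u = np.asarray(beam.direction)
    rel = pts - np.asarray(beam.isocenter)
    along = rel @ u
    # isocenter sits mid-plateau: depth(iso) = R - M/2
    depth = along + (beam.nominal_range_mm - 0.5 * beam.modulation_mm)
    perp = rel - np.outer(along, u)
    r2 = np.einsum("ij,ij->i", perp, perp)
    lateral = np.exp(-r2 / (2.0 * beam.lateral_sigma_mm**2))
    return beam.weight * lateral * depth_dose(
        depth, beam.nominal_range_mm, beam.modulation_mm, beam.falloff_sigma_mm, range_scale
    )


def _validate_scenario(shift: FractionShift | None, range_scale: float) -> FractionShift:
    lo, hi = _RANGE_SCALE_LIMITS
    if not (lo <= range_scale <= hi):
        raise ValidationError(f"range_scale must lie in [{lo}, {hi}], got {range_scale}")
    return shift if shift is not None else FractionShift.zero()


def dose_at_points(
    points: np.ndarray,
    beams: Sequence[BeamSpec],
    shift: FractionShift | None = None,
    range_scale: float = 1.0,
    isocenter: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Total dose (Gy) received by anatomy points under a rigid setup error.

    The shift moves the anatomy while the beams stay fixed, so the static
    beam model is evaluated at the transformed point positions.
    Deterministic for fixed inputs.
    """
    shift = _validate_scenario(shift, range_scale)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    moved = transform_points(pts, shift, np.asarray(isocenter, dtype=float))
    total = np.zeros(len(moved))
    for beam in beams:
        total += beam_dose_at_points(moved, beam, range_scale)
    return total


def compute_dose(
    phantom: Phantom,
    beams: Sequence[BeamSpec],
    shift: FractionShift | None = None,
    range_scale: float = 1.0,
) -> np.ndarray:
    """Dose grid (Gy per voxel, phantom grid shape) for one delivery scenario.

    Zero beams is allowed and yields an all-zero grid.
    """
    values = dose_at_points(
        phantom.grid.voxel_centers(), beams, shift, range_scale, phantom.isocenter
    )
    return values.reshape(phantom.grid.shape)


class NormalizedPlan(NamedTuple):
    beams: list[BeamSpec]
    scale: float


def normalize_plan(
    phantom: Phantom,
    beams: Sequence[BeamSpec],
    primary: Structure | None = None,
) -> NormalizedPlan:
    """Rescale all beam weights by one global factor so that the nominal
    (zero-shift, unit range scale) D95 of the primary target equals its
    prescription.

    Dose is linear in beam weights, so the factor is exact.
    """
    from ..dvh import d_at_volume  # local import to avoid a cycle

    if primary is None:
        primary = phantom.primary_target
    pts = phantom.structure_points(primary.name)
    nominal = dose_at_points(pts, beams, None, 1.0, phantom.isocenter)
    d95 = d_at_volume(nominal, None, 95.0, name=primary.name) if nominal.any() else 0.0
    if d95 <= 0.0:
        raise NormalizationError(
            f"nominal dose on primary target {primary.name!r} gives D95={d95}; "
            "cannot normalize"
        )
    factor = float(primary.prescription_Gy) / float(d95)
    scaled = [replace(b, weight=b.weight * factor) for b in beams]
    return NormalizedPlan(beams=scaled, scale=factor)


def calibrate_plan(
    phantom: Phantom,
    beams: Sequence[BeamSpec],
    max_iter: int = 6,
    tol_Gy: float = 0.005,
) -> NormalizedPlan:
    """Normalize the plan to all target prescriptions.

    The global factor pins the primary D95 (as :func:`normalize_plan`); in
    addition, for every secondary target with beams tagged ``target=<name>``
    those beams are rescaled so the secondary's nominal D95 meets its own
    prescription — a stand-in for simultaneous-integrated-boost optimization.
    Alternates the two normalizations until both D95s converge.
    """
    from ..dvh import d_at_volume
    from scipy.optimize import brentq

    secondaries = [s for s in phantom.structures if s.role == "secondary_target"]
    tagged = {
        s.name: [i for i, b in enumerate(beams) if b.target == s.name] for s in secondaries
    }
    secondaries = [s for s in secondaries if tagged[s.name]]
    current = list(beams)
    total_scale = 1.0
    for _ in range(max_iter):
        current, scale = normalize_plan(phantom, current)
        total_scale *= scale
        converged = abs(scale - 1.0) * 60.0 < tol_Gy
        for s in secondaries:
            pts = phantom.structure_points(s.name)
            idx = set(tagged[s.name])
            own = dose_at_points(
                pts, [current[i] for i in sorted(idx)], None, 1.0, phantom.isocenter
            )
            rest = dose_at_points(
                pts,
                [b for i, b in enumerate(current) if i not in idx],
                None,
                1.0,
                phantom.isocenter,
            )
            rx = float(s.prescription_Gy)

            def gap(f: float) -> float:
                return d_at_volume(rest + f * own, None, 95.0, name=s.name) - rx

            if gap(1.0) == 0.0:
                continue
            if own.max() <= 0:
                raise NormalizationError(
                    f"secondary target {s.name!r} receives no dose from its tagged beams"
                )
            if gap(1e-9) > 0:
                raise NormalizationError(
                    f"secondary target {s.name!r} already exceeds its prescription "
                    "from untagged beams alone; cannot calibrate downward"
                )
            f = brentq(gap, 1e-9, 1e6, xtol=1e-10)
            for i in sorted(idx):
                current[i] = replace(current[i], weight=current[i].weight * f)
            converged = converged and abs(gap(f)) < tol_Gy
        if converged:
            break
    return NormalizedPlan(beams=current, scale=total_scale)
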