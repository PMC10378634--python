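"""Cumulative DVHs and plan-quality metrics (D95%, V100%, Dmax, Dmean).

All metrics are computed from the raw voxel-dose list of a structure — the
binned :class:`DVHCurve` exists only for plotting and export.  Every voxel
carries equal weight (uniform grid).

Conventions, pinned by tests:

* ``d_at_volume`` interpolates linearly between the sorted-voxel order
  statistics bracketing fractional rank ``p * N / 100`` (``interpolate=False``
  selects the conservative nearest-rank value instead).
* ``v_at_dose`` counts voxels with dose >= threshold; ties count as covered.
* ``Dmax`` is the single hottest voxel — no D0.03cc-style clinical smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyStructureError, ValidationError

__all__ = [
    "DVHMetrics",
    "DVHCurve",
    "cumulative_dvh",
    "d_at_volume",
    "v_at_dose",
    "oar_metric",
]


def _voxel_doses(dose, mask, name: str | None) -> np.ndarray:
    """Extract the 1-D voxel-dose list; ``mask=None`` means ``dose`` already is one."""
    dose = np.asarray(dose, dtype=float)
    if mask is None:
        doses = dose.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != dose.shape:
            raise ValidationError(
                f"mask shape {mask.shape} does not match dose shape {dose.shape}"
            )
        doses = dose[mask]
    if doses.size == 0:
        raise EmptyStructureError(name or "<unnamed>")
    return doses


@dataclass(frozen=True)
class DVHCurve:
    """Binned cumulative DVH: percent of volume receiving >= each dose edge."""

    dose_edges: np.ndarray
    volume_pct: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "dose_edges", np.asarray(self.dose_edges, dtype=float))
        object.__setattr__(self, "volume_pct", np.asarray(self.volume_pct, dtype=float))


@dataclass(frozen=True)
class DVHMetrics:
    D95_Gy: float
    V100_pct: float
    Dmax_Gy: float
    Dmean_Gy: float

    @classmethod
    def from_dose(cls, dose, mask, prescription_Gy: float, name: str | None = None):
        doses = _voxel_doses(dose, mask, name)
        return cls(
            D95_Gy=d_at_volume(doses, None, 95.0, name=name),
            V100_pct=v_at_dose(doses, None, prescription_Gy, name=name),
            Dmax_Gy=float(doses.max()),
            Dmean_Gy=float(doses.mean()),
        )


def cumulative_dvh(dose, mask, bin_width_Gy: float, name: str | None = None) -> DVHCurve:
    """Volume-weighted cumulative dose-volume histogram.

    Edges run from 0 to one bin beyond the maximum dose, so the curve starts
    at 100% and ends at 0%.
    """
    if bin_width_Gy <= 0:
        raise ValidationError(f"bin width must be > 0, got {bin_width_Gy}")
    doses = _voxel_doses(dose, mask, name)
    top = math.floor(doses.max() / bin_width_Gy) + 1
    edges = np.arange(0, top + 1) * bin_width_Gy
    pct = np.array([v_at_dose(doses, None, e) for e in edges])
    return DVHCurve(dose_edges=edges, volume_pct=pct)


def d_at_volume(
    dose,
    mask,
    p_pct: float,
    interpolate: bool = True,
    name: str | None = None,
) -> float:
    """Dose received by at least ``p_pct`` percent of the structure volume.

    With ``interpolate=True`` the value is a linear blend of the descending
    order statistics bracketing fractional rank ``p * N / 100``; at integer
    ranks both conventions coincide.
    """
    if not (0.0 < p_pct <= 100.0):
        raise ValidationError(f"p_pct must lie in (0, 100], got {p_pct}")
    doses = _voxel_doses(dose, mask, name)
    desc = np.sort(doses)[::-1]
    n = desc.size
    rank = p_pct * n / 100.0
    if rank <= 1.0:
        return float(desc[0])
    k = int(math.floor(rank))
    frac = rank - k
    if not interpolate:
        return float(desc[int(math.ceil(rank)) - 1])
    if frac == 0.0 or k >= n:
        return float(desc[min(k, n) - 1])
    return float(desc[k - 1] + frac * (desc[k] - desc[k - 1]))


def v_at_dose(dose, mask, threshold_Gy: float, name: str | None = None) -> float:
    """Percent of structure volume receiving at least ``threshold_Gy``."""
    if threshold_Gy < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold_Gy}")
    doses = _voxel_doses(dose, mask, name)
    return 100.0 * float(np.count_nonzero(doses >= threshold_Gy)) / doses.size


def oar_metric(dose, mask, kind: str, name: str | None = None) -> float:
    """Maximum or mean voxel dose inside an OAR mask."""
    doses = _voxel_doses(dose, mask, name)
    if kind == "max":
        return float(doses.max())
    if kind == "mean":
        return float(doses.mean())
    raise ValidationError(f"unknown OAR metric kind {kind!r} (expected 'max' or 'mean')")
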