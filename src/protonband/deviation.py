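"""Per-fraction deviation analysis against robustness bands.

The two deviation rules:

* dose (D95): the excursion beyond the nearest violated bound, as a percent
  of the target prescription — ``100 * max(D_fx - D_Rmax, D_Rmin - D_fx) / D_Rx``
  when outside the band, 0 inside.
* volume (V100): the same excursion in percentage points of volume.

As printed, the source formulas take the *minimum* of the two signed
differences, which is negative for every out-of-band value; all reported
results describe absolute deviations, so the implementation returns the
positive magnitude (max of the two, clamped at 0).

OAR metrics (Dmax/Dmean) have no prescription to scale by; their excursion
is reported in Gy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BandStatus, ScenarioBand, fraction_metrics, metric_items, within_band
from .errors import ConfigurationError, ValidationError
from .synthetic.dose import BeamSpec
from .synthetic.phantom import Phantom
from .synthetic.shifts import FractionShift

__all__ = [
    "DeviationRecord",
    "DeviationSummary",
    "fractional_dose_deviation",
    "fractional_volume_deviation",
    "evaluate_fraction",
    "judge_metrics",
    "records_to_frame",
    "summarize",
    "summaries_to_frame",
]

_TIER = {"primary_target": "primary", "secondary_target": "secondary", "oar": "oar"}


def fractional_dose_deviation(
    D_fx: float, D_Rmin: float, D_Rmax: float, D_Rx: float
) -> float:
    """Out-of-band dose excursion as percent of prescription (0 inside)."""
    if D_Rx <= 0:
        raise ValidationError(f"prescription must be > 0, got {D_Rx}")
    if D_Rmin > D_Rmax:
        raise ValidationError(f"invalid band [{D_Rmin}, {D_Rmax}]")
    excursion = max(D_fx - D_Rmax, D_Rmin - D_fx, 0.0)
    return 100.0 * excursion / D_Rx


def fractional_volume_deviation(V_fx: float, V_Rmin: float, V_Rmax: float) -> float:
    """Out-of-band volume excursion in percentage points (0 inside)."""
    for label, v in (("V_fx", V_fx), ("V_Rmin", V_Rmin), ("V_Rmax", V_Rmax)):
        if not (0.0 <= v <= 100.0):
            raise ValidationError(f"{label} must lie in [0, 100] %, got {v}")
    if V_Rmin > V_Rmax:
        raise ValidationError(f"invalid band [{V_Rmin}, {V_Rmax}]")
    return max(V_fx - V_Rmax, V_Rmin - V_fx, 0.0)


@dataclass(frozen=True)
class DeviationRecord:
    """One fraction x structure x metric x setup-setting judgment."""

    patient: str
    fraction: int
    structure: str
    metric: str
    tier: str
    setup_mm: float
    value: float
    band_min: float
    band_max: float
    status: BandStatus
    deviation: float


def _deviation_for(metric: str, value: float, band: ScenarioBand, rx: float | None) -> float:
    if metric == "D95":
        return fractional_dose_deviation(value, band.band_min, band.band_max, float(rx))
    if metric == "V100":
        return fractional_volume_deviation(value, band.band_min, band.band_max)
    # OAR Gy excursion
    return max(value - band.band_max, band.band_min - value, 0.0)


def judge_metrics(
    metrics: Mapping[tuple[str, str], float],
    phantom: Phantom,
    bands_by_setup: Mapping[float, Mapping[tuple[str, str], ScenarioBand]],
    patient: str = "",
    fraction: int = 0,
) -> list[DeviationRecord]:
    """Judge precomputed structure/metric values against every setup's bands.

    Shared by the synthetic route (:func:`evaluate_fraction`) and externally
    supplied per-fraction dose grids.
    """
    records: list[DeviationRecord] = []
    for structure, metric in metric_items(phantom):
        key = (structure.name, metric)
        value = metrics[key]
        for setup_mm, bands in bands_by_setup.items():
            if key not in bands:
                raise ConfigurationError(
                    f"no {setup_mm} mm band for structure {structure.name!r} "
                    f"metric {metric!r}"
                )
            band = bands[key]
            status = within_band(value, band)
            deviation = _deviation_for(metric, value, band, structure.prescription_Gy)
            records.append(
                DeviationRecord(
                    patient=patient,
                    fraction=int(fraction),
                    structure=structure.name,
                    metric=metric,
                    tier=_TIER[structure.role],
                    setup_mm=float(setup_mm),
                    value=float(value),
                    band_min=band.band_min,
                    band_max=band.band_max,
                    status=status,
                    deviation=float(deviation),
                )
            )
    return records


def evaluate_fraction(
    phantom: Phantom,
    beams: Sequence[BeamSpec],
    bands_by_setup: Mapping[float, Mapping[tuple[str, str], ScenarioBand]],
    shift: FractionShift,
    patient: str = "",
    fraction: int = 0,
    points_cache: Mapping[str, np.ndarray] | None = None,
) -> list[DeviationRecord]:
    """Recompute one fraction's dose with its full 6-DOF error and judge every
    structure/metric against the bands of every setup setting.

    The daily recomputation uses range_scale 1: range error is a planning
    uncertainty, not a daily observable here.
    """
    metrics = fraction_metrics(phantom, beams, shift, 1.0, points_cache)
    return judge_metrics(metrics, phantom, bands_by_setup, patient, fraction)


_RECORD_COLUMNS = [
    "patient",
    "fraction",
    "structure",
    "metric",
    "tier",
    "setup_mm",
    "value",
    "band_min",
    "band_max",
    "status",
    "deviation",
]


def records_to_frame(records: Iterable[DeviationRecord]) -> pd.DataFrame:
    rows = [
        {c: (str(getattr(r, c)) if c == "status" else getattr(r, c)) for c in _RECORD_COLUMNS}
        for r in records
    ]
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


@dataclass(frozen=True)
class DeviationSummary:
    """Aggregate over one record group (class x tier x setup by default)."""

    group: dict
    n_records: int
    n_outside: int
    pct_outside: float
    pct_below_prescribed: float | None
    mean_deviation: float
    deviation_min: float
    deviation_max: float
    mean_deviation_all: float

    def to_dict(self) -> dict:
        d = dict(self.group)
        d.update(
            n_records=self.n_records,
            n_outside=self.n_outside,
            pct_outside=self.pct_outside,
            pct_below_prescribed=self.pct_below_prescribed,
            mean_deviation=self.mean_deviation,
            deviation_min=self.deviation_min,
            deviation_max=self.deviation_max,
            mean_deviation_all=self.mean_deviation_all,
        )
        return d


def summarize(
    records: pd.DataFrame | Iterable[DeviationRecord],
    class_map: Mapping[str, str] | None = None,
    group_by: Sequence[str] = ("patient_class", "tier", "setup_mm"),
    outside_only: bool = True,
) -> list[DeviationSummary]:
    """Aggregate deviation records into per-group summaries.

    ``class_map`` maps patient id -> treatment class (e.g. PO/PNN) and is
    required when grouping by ``patient_class``.  The headline mean/min/max
    deviation is taken over out-of-band records only (``outside_only=True``,
    the default); ``mean_deviation_all`` always averages over all records
    (zeros included) for sensitivity checks.  Groups with no out-of-band
    records report a mean of 0 with ``n_outside`` 0.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        warnings.warn("summarize called with no records; returning empty summary")
        return []
    df = df.copy()
    if "patient_class" in group_by:
        if "patient_class" not in df.columns:
            if class_map is None:
                raise ConfigurationError(
                    "grouping by patient_class requires a class_map or a "
                    "patient_class column"
                )
            df["patient_class"] = df["patient"].map(dict(class_map))
            if df["patient_class"].isna().any():
                missing = sorted(df.loc[df["patient_class"].isna(), "patient"].unique())
                raise ConfigurationError(f"patients missing from class_map: {missing}")
    out: list[DeviationSummary] = []
    for keys, grp in df.groupby(list(group_by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        outside = grp[grp["status"] != "inside"]
        devs = outside["deviation"] if outside_only else grp["deviation"]
        is_target = grp["tier"].isin(["primary", "secondary"])
        if is_target.any():
            tgt = grp[is_target]
            pct_below = 100.0 * float((tgt["status"] == "below").sum()) / len(tgt)
        else:
            pct_below = None
        out.append(
            DeviationSummary(
                group=dict(zip(group_by, keys)),
                n_records=int(len(grp)),
                n_outside=int(len(outside)),
                pct_outside=100.0 * len(outside) / len(grp),
                pct_below_prescribed=pct_below,
                mean_deviation=float(devs.mean()) if len(devs) else 0.0,
                deviation_min=float(devs.min()) if len(devs) else 0.0,
                deviation_max=float(devs.max()) if len(devs) else 0.0,
                mean_deviation_all=float(grp["deviation"].mean()),
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[DeviationSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])
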