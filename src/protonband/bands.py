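"""Setup/range uncertainty scenarios and min-max robustness bands.

A scenario pairs a rigid translation of the anatomy with a multiplicative
range scale.  For each structure/metric the band is the [min, max] envelope
of the metric over all scenarios; daily fractions are judged against it.
Rotational uncertainty is excluded from bands (robustness settings are
stated in mm only); rotations enter only through daily fraction errors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dvh import d_at_volume, oar_metric, v_at_dose
from .errors import ValidationError
from .synthetic.dose import BeamSpec, dose_at_points
from .synthetic.phantom import Phantom, Structure
from .synthetic.shifts import FractionShift

__all__ = [
    "SCENARIO_VARIANTS",
    "UncertaintyScenario",
    "ScenarioBand",
    "BandStatus",
    "enumerate_scenarios",
    "metric_items",
    "scenario_metrics",
    "compute_band",
    "compute_bands",
    "within_band",
]

#: selectable scenario-set conventions (shift count x 3 range scales)
SCENARIO_VARIANTS = ("axes", "separate", "corners")


@dataclass(frozen=True)
class UncertaintyScenario:
    """One robust-evaluation scenario: translation (mm) + range scale."""

    shift_mm: tuple[float, float, float]
    range_scale: float

    def __post_init__(self):
        if self.range_scale <= 0:
            raise ValidationError(f"range_scale must be > 0, got {self.range_scale}")
        object.__setattr__(self, "shift_mm", tuple(float(v) for v in self.shift_mm))

    @property
    def is_nominal(self) -> bool:
        return self.shift_mm == (0.0, 0.0, 0.0) and self.range_scale == 1.0

    def as_fraction_shift(self) -> FractionShift:
        return FractionShift(*self.shift_mm)


def enumerate_scenarios(
    setup_mm: float, range_delta: float, variant: str = "axes"
) -> list[UncertaintyScenario]:
    """Enumerate the deduplicated scenario set for one setup setting.

    Variants:

    * ``axes`` (default): 7 shift vectors {0, +-S along each axis} crossed
      with 3 range scales {1-d, 1, 1+d} -> 21 scenarios.
    * ``separate``: shifts and range perturbations are not combined -> the
      nominal, 6 axis shifts at scale 1, and 2 pure range scalings (9).
    * ``corners``: the 27 shift vectors {-S, 0, +S}^3 crossed with the 3
      range scales -> 81 scenarios.

    The nominal scenario (zero shift, scale 1) is always first.
    """
    if setup_mm < 0:
        raise ValidationError(f"setup_mm must be >= 0, got {setup_mm}")
    if not (0.0 <= range_delta <= 0.2):
        raise ValidationError(f"range_delta must lie in [0, 0.2], got {range_delta}")
    if variant not in SCENARIO_VARIANTS:
        raise ValidationError(f"unknown scenario variant {variant!r}")
    s = float(setup_mm)
    scales = [1.0, 1.0 - range_delta, 1.0 + range_delta]
    axis_shifts = [(0.0, 0.0, 0.0)]
    for ax in range(3):
        for sign in (+1.0, -1.0):
            v = [0.0, 0.0, 0.0]
            v[ax] = sign * s
            axis_shifts.append(tuple(v))
    if variant == "corners":
        shifts = [
            (sx, sy, sz)
            for sx in (0.0, s, -s)
            for sy in (0.0, s, -s)
            for sz in (0.0, s, -s)
        ]
        pairs = [(sh, sc) for sh in shifts for sc in scales]
    elif variant == "separate":
        pairs = [((0.0, 0.0, 0.0), sc) for sc in scales]
        pairs += [(sh, 1.0) for sh in axis_shifts[1:]]
    else:  # axes
        pairs = [(sh, sc) for sh in axis_shifts for sc in scales]
    seen: dict[tuple, UncertaintyScenario] = {}
    for sh, sc in pairs:
        key = (sh, sc)
        if key not in seen:
            seen[key] = UncertaintyScenario(shift_mm=sh, range_scale=sc)
    out = sorted(seen.values(), key=lambda sc: not sc.is_nominal)
    assert out[0].is_nominal
    return out


class BandStatus(str, enum.Enum):
    INSIDE = "inside"
    BELOW = "below"
    ABOVE = "above"

    def __str__(self) -> str:  # keep CSV output plain
        return self.value


@dataclass(frozen=True)
class ScenarioBand:
    """Min-max envelope of one structure/metric over a scenario set."""

    structure: str
    metric: str
    setup_mm: float
    band_min: float
    band_max: float
    nominal: float

    def __post_init__(self):
        if not (self.band_min <= self.nominal <= self.band_max):
            raise ValidationError(
                f"band for {self.structure}/{self.metric} must contain the nominal: "
                f"[{self.band_min}, {self.band_max}] vs {self.nominal}"
            )


def within_band(value: float, band: ScenarioBand) -> BandStatus:
    """Closed-interval membership: values exactly on a bound count as inside."""
    if value < band.band_min:
        return BandStatus.BELOW
    if value > band.band_max:
        return BandStatus.ABOVE
    return BandStatus.INSIDE


def metric_items(phantom: Phantom) -> list[tuple[Structure, str]]:
    """The (structure, metric) pairs analyzed for a phantom.

    Targets contribute D95 and V100; OARs contribute Dmax or Dmean per
    their metric kind.
    """
    items: list[tuple[Structure, str]] = []
    for s in phantom.structures:
        if s.is_target:
            items.append((s, "D95"))
            items.append((s, "V100"))
        elif s.metric_kind == "oar_max":
            items.append((s, "Dmax"))
        else:
            items.append((s, "Dmean"))
    return items


def _metric_value(doses: np.ndarray, structure: Structure, metric: str) -> float:
    if metric == "D95":
        return d_at_volume(doses, None, 95.0, name=structure.name)
    if metric == "V100":
        return v_at_dose(doses, None, float(structure.prescription_Gy), name=structure.name)
    if metric == "Dmax":
        return oar_metric(doses, None, "max", name=structure.name)
    if metric == "Dmean":
        return oar_metric(doses, None, "mean", name=structure.name)
    raise ValidationError(f"unknown metric {metric!r}")


def fraction_metrics(
    phantom: Phantom,
    beams: Sequence[BeamSpec],
    shift: FractionShift | None = None,
    range_scale: float = 1.0,
    points_cache: Mapping[str, np.ndarray] | None = None,
) -> dict[tuple[str, str], float]:
    """All structure/metric values for one delivery scenario.

    Dose is evaluated only at structure voxels (the metrics need nothing
    else), which keeps scenario sweeps cheap.
    """
    out: dict[tuple[str, str], float] = {}
    per_structure: dict[str, np.ndarray] = {}
    for structure, metric in metric_items(phantom):
        if structure.name not in per_structure:
            pts = (
                points_cache[structure.name]
                if points_cache is not None
                else phantom.structure_points(structure.name)
            )
            per_structure[structure.name] = dose_at_points(
                pts, beams, shift, range_scale, phantom.isocenter
            )
        out[(structure.name, metric)] = _metric_value(
            per_structure[structure.name], structure, metric
        )
    return out


def scenario_metrics(
    phantom: Phantom,
    beams: Sequence[BeamSpec],
    scenario: UncertaintyScenario,
    points_cache: Mapping[str, np.ndarray] | None = None,
) -> dict[tuple[str, str], float]:
    return fraction_metrics(
        phantom, beams, scenario.as_fraction_shift(), scenario.range_scale, points_cache
    )


def compute_bands(
    phantom: Phantom,
    beams: Sequence[BeamSpec],
    scenarios: Sequence[UncertaintyScenario],
    setup_mm: float,
) -> dict[tuple[str, str], ScenarioBand]:
    """Evaluate every structure/metric under every scenario and envelope them."""
    if not scenarios:
        raise ValidationError("scenario list must be nonempty")
    if not any(sc.is_nominal for sc in scenarios):
        raise ValidationError("scenario list must include the nominal scenario")
    cache = {s.name: phantom.structure_points(s.name) for s in phantom.structures}
    tables = [scenario_metrics(phantom, beams, sc, cache) for sc in scenarios]
    nominal_table = tables[[sc.is_nominal for sc in scenarios].index(True)]
    bands: dict[tuple[str, str], ScenarioBand] = {}
    for structure, metric in metric_items(phantom):
        key = (structure.name, metric)
        values = [t[key] for t in tables]
        bands[key] = ScenarioBand(
            structure=structure.name,
            metric=metric,
            setup_mm=float(setup_mm),
            band_min=float(min(values)),
            band_max=float(max(values)),
            nominal=float(nominal_table[key]),
        )
    return bands


def compute_band(
    phantom: Phantom,
    beams: Sequence[BeamSpec],
    structure: Structure | str,
    metric: str,
    scenarios: Sequence[UncertaintyScenario],
    setup_mm: float = float("nan"),
) -> ScenarioBand:
    """Band for a single structure/metric (convenience over :func:`compute_bands`)."""
    name = structure if isinstance(structure, str) else structure.name
    return compute_bands(phantom, beams, scenarios, setup_mm)[(name, metric)]
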