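"""Cohort configuration: schema, (de)serialization, and the default cohort.

A cohort config is plain data (YAML/JSON friendly) describing the grid,
per-patient structure solids, beams, prescriptions, fraction counts and
shift distributions.  Randomness is controlled by one root seed; the
per-patient substream is derived with ``SeedSequence([root_seed,
patient_index])`` so cohorts are reproducible regardless of execution
order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ..errors import ConfigurationError
from .dose import BeamSpec
from .phantom import Phantom, build_phantom
from .shifts import AXES, FractionShift, ShiftDistribution, sample_fraction_shifts

__all__ = [
    "PatientConfig",
    "CohortConfig",
    "default_cohort",
    "build_patient_phantom",
    "patient_beams",
    "patient_shift_rng",
    "sample_patient_shifts",
]


@dataclass
class PatientConfig:
    """One synthetic patient: geometry, plan and daily-error model."""

    id: str
    patient_class: str  # "PO" or "PNN"
    n_fractions: int
    structures: list[dict]
    beams: list[dict]
    shift_sd: dict
    shift_mean: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.patient_class not in ("PO", "PNN"):
            raise ConfigurationError(
                f"patient {self.id!r}: class must be PO or PNN, got {self.patient_class!r}"
            )
        if self.n_fractions < 1:
            raise ConfigurationError(f"patient {self.id!r}: n_fractions must be >= 1")
        unknown = set(self.shift_sd) - set(AXES)
        unknown |= set(self.shift_mean) - set(AXES)
        if unknown:
            raise ConfigurationError(
                f"patient {self.id!r}: unknown shift axes {sorted(unknown)}"
            )

    def shift_distribution(self, seed: int | None = None) -> ShiftDistribution:
        sd = tuple(float(self.shift_sd.get(a, 0.0)) for a in AXES)
        mean = tuple(float(self.shift_mean.get(a, 0.0)) for a in AXES)
        return ShiftDistribution(sd=sd, mean=mean, seed=seed)


@dataclass
class CohortConfig:
    """The full synthetic cohort: shared grid plus per-patient plans."""

    grid: dict
    patients: list[PatientConfig]
    seed: int = 0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not self.patients:
            raise ConfigurationError("cohort has no patients")
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate patient ids: {ids}")

    @property
    def class_map(self) -> dict[str, str]:
        return {p.id: p.patient_class for p in self.patients}

    # --- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        data = {
            "grid": dict(self.grid),
            "seed": int(self.seed),
            "isocenter_mm": list(self.isocenter_mm),
            "patients": [asdict(p) for p in self.patients],
        }
        # normalize tuples to lists so YAML/JSON round trips are exact
        return json.loads(json.dumps(data))

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        try:
            patients = [PatientConfig(**p) for p in data["patients"]]
            return cls(
                grid=dict(data["grid"]),
                patients=patients,
                seed=int(data.get("seed", 0)),
                isocenter_mm=tuple(data.get("isocenter_mm", (0.0, 0.0, 0.0))),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"invalid cohort config: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def build_patient_phantom(cohort: CohortConfig, patient: PatientConfig) -> Phantom:
    return build_phantom(
        {
            "grid": cohort.grid,
            "structures": patient.structures,
            "isocenter_mm": cohort.isocenter_mm,
        }
    )


def patient_beams(patient: PatientConfig) -> list[BeamSpec]:
    return [BeamSpec(**b) for b in patient.beams]


def patient_shift_rng(root_seed: int, patient_index: int) -> np.random.Generator:
    """Stable per-patient substream: SeedSequence([root_seed, patient_index])."""
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), int(patient_index)]))


def sample_patient_shifts(
    cohort: CohortConfig, patient_index: int, seed: int | None = None
) -> list[FractionShift]:
    """Draw the patient's full course of daily setup errors, reproducibly."""
    root = cohort.seed if seed is None else seed
    patient = cohort.patients[patient_index]
    rng = patient_shift_rng(root, patient_index)
    return sample_fraction_shifts(patient.n_fractions, patient.shift_distribution(), rng=rng)


# --- default cohort ---------------------------------------------------------

# Beam shape shared by all default fields.  The modulated plateau comfortably
# covers the targets in depth; the distal edge (logistic, sigma 3.5 mm) lands
# inside the phantom so range scaling is observable.
_BEAM_COMMON = dict(
    nominal_range_mm=70.0,
    modulation_mm=36.0,
    falloff_sigma_mm=3.5,
)

# Daily-error model.  PO-like patients have larger translations than
# PNN-like ones (the observed class difference in couch-shift magnitudes);
# rotations — dominated by roll/pitch — are substantial for both, which is
# what makes elongated targets fragile.
_PO_SD = {"tx": 2.6, "ty": 2.6, "tz": 2.6, "yaw": 1.6, "roll": 2.4, "pitch": 2.0}
_PNN_SD = {"tx": 1.5, "ty": 1.5, "tz": 1.5, "yaw": 1.2, "roll": 4.5, "pitch": 2.0}

_PO_FRACTIONS = [42, 38]
_PNN_FRACTIONS = [33, 30, 32, 28]  # cohort total 203 fractions

# Spot-row layout: rows of +y fields stacked along z paint each target.
# The primary row is short and forgiving (sigma 15 mm); the nodal row is
# long and sharp (sigma 8 mm), so rotations about the isocenter displace
# its far ends into the penumbra while barely moving the primary.
_PRIMARY_SPOT_Z = (-10.0, 0.0, 10.0)
_PRIMARY_SIGMA = 15.0
# The row is deliberately asymmetric: the two extra superior spots keep the
# superior tip warm under any scenario shift up to 5 mm, so the inferior tip
# is the unique cold end and the band envelopes stay monotone in the setup
# magnitude (two competing cold ends give the D95 quantile an interior
# maximum under axial shifts, which would break band nesting).
_NODAL_SPOT_Z = (-45.5, -32.5, -19.5, -6.5, 6.5, 19.5, 32.5, 45.5, 58.5, 71.5)
_NODAL_SIGMA = 8.0
_NODAL_X = -41.0


def _default_patient_geometry(
    rng: np.random.Generator, with_nodal: bool
) -> tuple[list[dict], list[dict]]:
    """Anatomy template with mild per-patient jitter (centers +-1 mm, radii
    +-0.5 mm) and spot rows aimed at the jittered target centers, as a
    clinical plan would be.

    Placement keeps every structure's cold-dose region clear of the other
    targets' penumbras (>= 3 sigma in the lateral plane), so scenario bands
    stay monotone in the setup-uncertainty magnitude.
    """

    def j(x, scale=1.0):
        return float(x + rng.uniform(-scale, scale))

    primary_center = [j(0.0), j(0.0), j(0.0)]
    structures = [
        {
            "name": "ctv_primary",
            "role": "primary_target",
            "shape": "capsule",
            "center_mm": list(primary_center),
            "radius_mm": j(12.0, 0.5),
            "half_length_mm": j(18.0, 0.5),
            "axis": "z",
            "prescription_Gy": 60.0,
        },
        {
            "name": "spinal_cord",
            "role": "oar",
            "shape": "cylinder",
            "center_mm": [j(-28.0), j(18.0), 0.0],
            "radius_mm": j(5.0, 0.5),
            "half_length_mm": 65.0,
            "axis": "z",
            "metric_kind": "oar_max",
        },
        {
            "name": "brainstem",
            "role": "oar",
            "shape": "ellipsoid",
            "center_mm": [j(-24.0), j(-8.0), j(48.0)],
            "radii_mm": [j(8.0, 0.5), j(8.0, 0.5), j(11.0, 0.5)],
            "metric_kind": "oar_max",
        },
        {
            "name": "parotid_l",
            "role": "oar",
            "shape": "ellipsoid",
            "center_mm": [j(38.0), j(8.0), j(10.0)],
            "radii_mm": [j(7.0, 0.5), j(9.0, 0.5), j(13.0, 0.5)],
            "metric_kind": "oar_mean",
        },
        {
            "name": "parotid_r",
            "role": "oar",
            "shape": "ellipsoid",
            "center_mm": [j(-26.0), j(20.0), j(10.0)],
            "radii_mm": [j(7.0, 0.5), j(9.0, 0.5), j(13.0, 0.5)],
            "metric_kind": "oar_mean",
        },
    ]
    beams = [
        dict(
            direction=(0.0, 1.0, 0.0),
            isocenter=[primary_center[0], primary_center[1], primary_center[2] + zk],
            lateral_sigma_mm=_PRIMARY_SIGMA,
            weight=1.0,
            **_BEAM_COMMON,
        )
        for zk in _PRIMARY_SPOT_Z
    ]
    if with_nodal:
        # elongated superior-inferior nodal chain, offset laterally
        nodal_center = [j(_NODAL_X), j(0.0), j(0.0)]
        structures.insert(
            1,
            {
                "name": "ctv_nodal",
                "role": "secondary_target",
                "shape": "capsule",
                "center_mm": list(nodal_center),
                "radius_mm": j(8.0, 0.5),
                "half_length_mm": j(52.0, 0.5),
                "axis": "z",
                "prescription_Gy": 54.0,
            },
        )
        # the long spot row is tagged for SIB-style calibration
        for zk in _NODAL_SPOT_Z:
            beams.append(
                dict(
                    direction=(0.0, 1.0, 0.0),
                    isocenter=[nodal_center[0], nodal_center[1], nodal_center[2] + zk],
                    lateral_sigma_mm=_NODAL_SIGMA,
                    weight=0.4,
                    target="ctv_nodal",
                    **_BEAM_COMMON,
                )
            )
    return structures, beams


def default_cohort(seed: int = 1234) -> CohortConfig:
    """The 6-patient default cohort: 2 PO-like and 4 PNN-like patients,
    203 fractions in total, on a 44x44x60 grid at 2.5 mm spacing."""
    patients: list[PatientConfig] = []
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 982451653]))
    for i, nfx in enumerate(_PO_FRACTIONS):
        structures, beams = _default_patient_geometry(rng, with_nodal=False)
        patients.append(
            PatientConfig(
                id=f"PO-{i + 1:02d}",
                patient_class="PO",
                n_fractions=nfx,
                structures=structures,
                beams=beams,
                shift_sd=dict(_PO_SD),
            )
        )
    for i, nfx in enumerate(_PNN_FRACTIONS):
        structures, beams = _default_patient_geometry(rng, with_nodal=True)
        patients.append(
            PatientConfig(
                id=f"PNN-{i + 1:02d}",
                patient_class="PNN",
                n_fractions=nfx,
                structures=structures,
                beams=beams,
                shift_sd=dict(_PNN_SD),
            )
        )
    return CohortConfig(
        grid={"shape": [44, 44, 60], "spacing_mm": [2.5, 2.5, 2.5], "origin_mm": None},
        patients=patients,
        seed=int(seed),
    )
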