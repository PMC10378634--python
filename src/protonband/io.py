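"""File formats: hashed CSV tables, NIfTI grids, and cohort export/import.

The import path lets users substitute externally recomputed per-fraction
dose grids (NIfTI) plus masks, bands and shift logs for the synthetic dose
model, keeping the downstream deviation analysis identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .bands import ScenarioBand
from .errors import (
    ConfigurationError,
    GeometryMismatchError,
    MissingFractionsError,
    ValidationError,
)
from .geometry import GridSpec
from .synthetic.phantom import Phantom, Structure
from .synthetic.shifts import AXES, FractionShift

__all__ = [
    "write_table",
    "read_table",
    "save_nifti",
    "load_nifti",
    "shift_log_frame",
    "export_cohort_patient",
    "ImportedPatient",
    "import_cohort",
]

SHIFT_LOG_COLUMNS = [
    "patient",
    "fraction",
    "tx_mm",
    "ty_mm",
    "tz_mm",
    "yaw_deg",
    "roll_deg",
    "pitch_deg",
]

BAND_COLUMNS = ["patient", "structure", "metric", "setup_mm", "band_min", "band_max", "nominal"]


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """CSV with an optional ``# config_hash=...`` comment header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_nifti(data: np.ndarray, grid: GridSpec, path: str | Path, dtype=np.float32) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), grid.affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValidationError(f"{path}: only axis-aligned (diagonal) affines are supported")
    grid = GridSpec(
        tuple(int(s) for s in img.shape[:3]),
        tuple(float(v) for v in np.diag(aff[:3, :3])),
        tuple(float(v) for v in aff[:3, 3]),
    )
    return np.asanyarray(img.dataobj).astype(float), grid


def shift_log_frame(patient: str, shifts: Sequence[FractionShift]) -> pd.DataFrame:
    rows = [
        {
            "patient": patient,
            "fraction": i,
            "tx_mm": s.tx,
            "ty_mm": s.ty,
            "tz_mm": s.tz,
            "yaw_deg": s.yaw,
            "roll_deg": s.roll,
            "pitch_deg": s.pitch,
        }
        for i, s in enumerate(shifts)
    ]
    return pd.DataFrame(rows, columns=SHIFT_LOG_COLUMNS)


def _shifts_from_log(df: pd.DataFrame, patient: str) -> list[FractionShift]:
    sub = df[df["patient"] == patient].sort_values("fraction")
    if sub.empty:
        raise MissingFractionsError(f"no shift rows for patient {patient!r}")
    fractions = sub["fraction"].to_numpy()
    expected = np.arange(len(fractions))
    if not np.array_equal(fractions, expected):
        gaps = sorted(set(range(int(fractions.max()) + 1)) - set(fractions.tolist()))
        raise MissingFractionsError(
            f"patient {patient!r}: shift log is missing fractions {gaps}"
        )
    return [
        FractionShift(
            tx=r.tx_mm, ty=r.ty_mm, tz=r.tz_mm,
            yaw=r.yaw_deg, roll=r.roll_deg, pitch=r.pitch_deg,
        )
        for r in sub.itertuples()
    ]


def bands_frame(
    patient: str, bands_by_setup: Mapping[float, Mapping[tuple[str, str], ScenarioBand]]
) -> pd.DataFrame:
    rows = []
    for setup_mm in sorted(bands_by_setup):
        for band in bands_by_setup[setup_mm].values():
            rows.append(
                {
                    "patient": patient,
                    "structure": band.structure,
                    "metric": band.metric,
                    "setup_mm": band.setup_mm,
                    "band_min": band.band_min,
                    "band_max": band.band_max,
                    "nominal": band.nominal,
                }
            )
    return pd.DataFrame(rows, columns=BAND_COLUMNS)


def bands_from_frame(df: pd.DataFrame) -> dict[float, dict[tuple[str, str], ScenarioBand]]:
    out: dict[float, dict[tuple[str, str], ScenarioBand]] = {}
    for r in df.itertuples():
        band = ScenarioBand(
            structure=r.structure,
            metric=r.metric,
            setup_mm=float(r.setup_mm),
            band_min=float(r.band_min),
            band_max=float(r.band_max),
            nominal=float(r.nominal),
        )
        out.setdefault(float(r.setup_mm), {})[(r.structure, r.metric)] = band
    return out


# --- cohort export / import -------------------------------------------------


def export_cohort_patient(
    outdir: str | Path,
    patient_id: str,
    patient_class: str,
    phantom: Phantom,
    bands_by_setup: Mapping[float, Mapping[tuple[str, str], ScenarioBand]],
    fraction_doses: Sequence[np.ndarray],
    config_hash: str | None = None,
) -> Path:
    """Write one patient's masks, plan metadata, bands and per-fraction dose
    grids under ``outdir/patients/<id>/``.  Dose is float32 Gy, masks uint8."""
    pdir = Path(outdir) / "patients" / patient_id
    (pdir / "masks").mkdir(parents=True, exist_ok=True)
    (pdir / "fractions").mkdir(parents=True, exist_ok=True)
    meta = {
        "patient": patient_id,
        "patient_class": patient_class,
        "isocenter_mm": list(phantom.isocenter),
        "n_fractions": len(fraction_doses),
        "structures": [
            {
                "name": s.name,
                "role": s.role,
                "prescription_Gy": s.prescription_Gy,
                "metric_kind": s.metric_kind,
            }
            for s in phantom.structures
        ],
    }
    (pdir / "plan.json").write_text(json.dumps(meta, indent=2))
    for s in phantom.structures:
        save_nifti(s.mask.astype(np.uint8), phantom.grid, pdir / "masks" / f"{s.name}.nii.gz",
                   dtype=np.uint8)
    write_table(bands_frame(patient_id, bands_by_setup), pdir / "bands.csv", config_hash)
    for i, dose in enumerate(fraction_doses):
        save_nifti(dose, phantom.grid, pdir / "fractions" / f"fx_{i:03d}.nii.gz")
    return pdir


@dataclass
class ImportedPatient:
    """Externally supplied inputs for one patient, geometry-checked."""

    id: str
    patient_class: str
    phantom: Phantom
    bands_by_setup: dict[float, dict[tuple[str, str], ScenarioBand]]
    shifts: list[FractionShift]
    fraction_doses: list[np.ndarray]


def _check_geometry(grid: GridSpec, other: GridSpec, what: str) -> None:
    if not grid.same_geometry(other):
        raise GeometryMismatchError(
            f"{what}: grid geometry mismatch\n  expected: {grid}\n  got:      {other}"
        )


def import_cohort(indir: str | Path) -> list[ImportedPatient]:
    """Load a cohort previously written by :func:`export_cohort_patient`
    (plus the cohort-level ``shifts.csv``)."""
    indir = Path(indir)
    shifts_path = indir / "shifts.csv"
    if not shifts_path.exists():
        raise ConfigurationError(f"missing shift log {shifts_path}")
    shift_log = read_table(shifts_path)
    missing = set(SHIFT_LOG_COLUMNS) - set(shift_log.columns)
    if missing:
        raise ValidationError(f"shift log lacks columns {sorted(missing)}")
    patients: list[ImportedPatient] = []
    pdirs = sorted((indir / "patients").iterdir()) if (indir / "patients").exists() else []
    if not pdirs:
        raise ConfigurationError(f"no patients/ directory under {indir}")
    for pdir in pdirs:
        meta = json.loads((pdir / "plan.json").read_text())
        pid = meta["patient"]
        structures: list[Structure] = []
        grid: GridSpec | None = None
        for smeta in meta["structures"]:
            mask, mgrid = load_nifti(pdir / "masks" / f"{smeta['name']}.nii.gz")
            if grid is None:
                grid = mgrid
            else:
                _check_geometry(grid, mgrid, f"{pid}/masks/{smeta['name']}")
            structures.append(
                Structure(
                    name=smeta["name"],
                    role=smeta["role"],
                    mask=mask > 0,
                    prescription_Gy=smeta.get("prescription_Gy"),
                    metric_kind=smeta.get("metric_kind", ""),
                )
            )
        assert grid is not None
        phantom = Phantom(
            grid=grid,
            structures=structures,
            isocenter=tuple(meta.get("isocenter_mm", (0.0, 0.0, 0.0))),
        )
        bands = bands_from_frame(read_table(pdir / "bands.csv"))
        shifts = _shifts_from_log(shift_log, pid)
        n_fx = int(meta["n_fractions"])
        if len(shifts) != n_fx:
            raise MissingFractionsError(
                f"patient {pid!r}: plan declares {n_fx} fractions, "
                f"shift log has {len(shifts)}"
            )
        doses = []
        for i in range(n_fx):
            fpath = pdir / "fractions" / f"fx_{i:03d}.nii.gz"
            if not fpath.exists():
                raise MissingFractionsError(
                    f"patient {pid!r}: missing dose grid for fraction {i} ({fpath.name})"
                )
            dose, dgrid = load_nifti(fpath)
            _check_geometry(grid, dgrid, f"{pid}/fractions/fx_{i:03d}")
            doses.append(dose)
        patients.append(
            ImportedPatient(
                id=pid,
                patient_class=meta["patient_class"],
                phantom=phantom,
                bands_by_setup=bands,
                shifts=shifts,
                fraction_doses=doses,
            )
        )
    return patients
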