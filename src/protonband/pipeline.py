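"""End-to-end orchestration: cohort generation -> plan normalization -> band
construction -> per-fraction evaluation -> deviation summaries -> statistics
-> report files.

Deterministic under a fixed root seed: all randomness flows through the
cohort seed and the per-patient substream scheme, and every output table
embeds a hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .bands import ScenarioBand, compute_bands, enumerate_scenarios
from .deviation import (
    DeviationRecord,
    DeviationSummary,
    evaluate_fraction,
    judge_metrics,
    records_to_frame,
    summaries_to_frame,
    summarize,
)
from .dvh import d_at_volume, oar_metric, v_at_dose
from .errors import ConfigurationError, DegenerateSampleError
from .stats import StatResult, paired_one_sided_ttest, shift_comparisons, two_sample_ttest
from .synthetic.config import (
    CohortConfig,
    build_patient_phantom,
    default_cohort,
    patient_beams,
    sample_patient_shifts,
)
from .synthetic.dose import calibrate_plan, compute_dose
from .synthetic.phantom import Phantom
from .synthetic.shifts import FractionShift

__all__ = [
    "RunConfig",
    "PatientResult",
    "RunResult",
    "run_patient",
    "run_cohort",
    "evaluate_imported",
]

log = logging.getLogger("protonband")


@dataclass
class RunConfig:
    """Resolved run settings (cohort + uncertainty model + outputs)."""

    cohort: CohortConfig
    setup_mm: tuple[float, ...] = (3.0, 5.0)
    range_delta: float = 0.035
    scenario_variant: str = "axes"
    outdir: Path | None = None
    seed: int | None = None
    make_figures: bool = True
    export_grids: bool = False

    def __post_init__(self):
        self.setup_mm = tuple(float(s) for s in self.setup_mm)
        if not self.setup_mm or any(s <= 0 for s in self.setup_mm):
            raise ConfigurationError(
                f"setup_mm must be a nonempty list of positive values, got {self.setup_mm}"
            )
        if not (0.0 <= self.range_delta <= 0.2):
            raise ConfigurationError(
                f"range_delta must lie in [0, 0.2], got {self.range_delta}"
            )
        if self.outdir is not None:
            self.outdir = Path(self.outdir)

    @property
    def root_seed(self) -> int:
        return int(self.cohort.seed if self.seed is None else self.seed)

    def to_dict(self) -> dict:
        return {
            "setup_mm": list(self.setup_mm),
            "range_delta": self.range_delta,
            "scenario_variant": self.scenario_variant,
            "seed": self.root_seed,
            "cohort": self.cohort.to_dict(),
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: Mapping, **overrides) -> "RunConfig":
        cohort = data.get("cohort", "default")
        if cohort == "default" or cohort is None:
            cohort_cfg = default_cohort(seed=int(data.get("seed", 1234)))
        elif isinstance(cohort, Mapping):
            cohort_cfg = CohortConfig.from_dict(cohort)
        else:
            cohort_cfg = CohortConfig.from_file(cohort)
        kwargs = dict(
            cohort=cohort_cfg,
            setup_mm=tuple(data.get("setup_mm", (3.0, 5.0))),
            range_delta=float(data.get("range_delta", 0.035)),
            scenario_variant=data.get("scenario_variant", "axes"),
            seed=data.get("seed"),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"run config {path} must be a mapping")
        return cls.from_dict(data, **overrides)


@dataclass
class PatientResult:
    id: str
    patient_class: str
    phantom: Phantom
    beams: list
    plan_scale: float
    bands_by_setup: dict[float, dict[tuple[str, str], ScenarioBand]]
    shifts: list[FractionShift]
    records: list[DeviationRecord]


@dataclass
class RunResult:
    config: RunConfig
    config_hash: str
    patients: list[PatientResult]
    bands: pd.DataFrame
    records: pd.DataFrame
    shift_log: pd.DataFrame
    summaries: list[DeviationSummary]
    stats: list[StatResult]
    failures: list[str] = field(default_factory=list)

    @property
    def class_map(self) -> dict[str, str]:
        return {p.id: p.patient_class for p in self.patients}


def run_patient(
    cohort: CohortConfig,
    index: int,
    setup_mm: Sequence[float],
    range_delta: float,
    scenario_variant: str = "axes",
    seed: int | None = None,
) -> PatientResult:
    """Full per-patient pipeline: phantom, normalized plan, bands, fractions."""
    pcfg = cohort.patients[index]
    t0 = time.perf_counter()
    phantom = build_patient_phantom(cohort, pcfg)
    beams, scale = calibrate_plan(phantom, patient_beams(pcfg))
    cache = {s.name: phantom.structure_points(s.name) for s in phantom.structures}
    bands_by_setup = {
        float(s): compute_bands(
            phantom, beams, enumerate_scenarios(s, range_delta, scenario_variant), s
        )
        for s in setup_mm
    }
    shifts = sample_patient_shifts(cohort, index, seed=seed)
    records: list[DeviationRecord] = []
    for i, shift in enumerate(shifts):
        records.extend(
            evaluate_fraction(
                phantom, beams, bands_by_setup, shift,
                patient=pcfg.id, fraction=i, points_cache=cache,
            )
        )
    log.info(
        "patient %s: %d fractions, %d records in %.2f s",
        pcfg.id, len(shifts), len(records), time.perf_counter() - t0,
    )
    return PatientResult(
        id=pcfg.id,
        patient_class=pcfg.patient_class,
        phantom=phantom,
        beams=beams,
        plan_scale=scale,
        bands_by_setup=bands_by_setup,
        shifts=shifts,
        records=records,
    )


def _magnitude_log(shift_log: pd.DataFrame) -> pd.DataFrame:
    df = shift_log.copy()
    df["magnitude_mm"] = np.sqrt(df.tx_mm**2 + df.ty_mm**2 + df.tz_mm**2)
    return df


def compute_run_stats(
    records: pd.DataFrame,
    shift_log: pd.DataFrame,
    class_map: Mapping[str, str],
    setup_mm: Sequence[float],
) -> list[StatResult]:
    """The cohort-level test battery.

    Degenerate groups (too few out-of-band records, single-class cohorts)
    are skipped with a warning rather than failing the run.
    """
    results: list[StatResult] = list(
        shift_comparisons(_magnitude_log(shift_log), class_map)
    )
    df = records.copy()
    df["patient_class"] = df["patient"].map(dict(class_map))
    out = df[df["status"] != "inside"]

    def _try(fn, *args, **kwargs):
        try:
            results.append(fn(*args, **kwargs))
        except DegenerateSampleError as exc:
            warnings.warn(f"skipping {kwargs.get('name', fn.__name__)}: {exc}")

    for setup in setup_mm:
        for metric in ("D95", "V100"):
            sub = out[(out["setup_mm"] == float(setup)) & (out["metric"] == metric)]
            po = sub.loc[sub["patient_class"] == "PO", "deviation"]
            pnn = sub.loc[sub["patient_class"] == "PNN", "deviation"]
            if len(po) >= 2 and len(pnn) >= 2:
                _try(
                    two_sample_ttest, po, pnn,
                    name=f"deviation_{metric}_PO_vs_PNN_{setup:g}mm",
                    groups=("PO", "PNN"),
                )
            pnn_sub = sub[sub["patient_class"] == "PNN"]
            prim = pnn_sub.loc[pnn_sub["tier"] == "primary", "deviation"]
            sec = pnn_sub.loc[pnn_sub["tier"] == "secondary", "deviation"]
            if len(prim) >= 2 and len(sec) >= 2:
                _try(
                    two_sample_ttest, prim, sec,
                    name=f"deviation_{metric}_primary_vs_secondary_{setup:g}mm",
                    groups=("primary", "secondary"),
                )

    setups = sorted(float(s) for s in setup_mm)
    if len(setups) >= 2:
        lo, hi = setups[0], setups[-1]
        inside = (
            df.assign(inside=(df["status"] == "inside").astype(float))
            .groupby(["patient", "structure", "metric", "setup_mm"])["inside"]
            .mean()
            .unstack("setup_mm")
        )
        if lo in inside.columns and hi in inside.columns:
            x = 100.0 * inside[lo].to_numpy()
            y = 100.0 * inside[hi].to_numpy()
            if len(x) >= 2 and not np.all(x == y):
                _try(
                    paired_one_sided_ttest, x, y,
                    alternative="less",
                    name=f"within_robustness_{lo:g}mm_lt_{hi:g}mm",
                    groups=(f"{lo:g}mm", f"{hi:g}mm"),
                )
    return results


def run_cohort(config: RunConfig) -> RunResult:
    """Run the whole pipeline and (optionally) write all artifacts."""
    cohort = config.cohort
    patients: list[PatientResult] = []
    failures: list[str] = []
    for i in range(len(cohort.patients)):
        try:
            patients.append(
                run_patient(
                    cohort, i, config.setup_mm, config.range_delta,
                    config.scenario_variant, seed=config.root_seed,
                )
            )
        except Exception as exc:  # keep going; reflect failures in the result
            pid = cohort.patients[i].id
            log.error("patient %s failed: %s", pid, exc)
            failures.append(f"{pid}: {exc}")
    if not patients:
        raise ConfigurationError(f"every patient failed: {failures}")

    records = records_to_frame([r for p in patients for r in p.records])
    bands = pd.concat(
        [pio.bands_frame(p.id, p.bands_by_setup) for p in patients], ignore_index=True
    )
    shift_log = pd.concat(
        [pio.shift_log_frame(p.id, p.shifts) for p in patients], ignore_index=True
    )
    class_map = {p.id: p.patient_class for p in patients}
    summaries = summarize(records, class_map=class_map)
    summaries += summarize(
        records, class_map=class_map, group_by=("patient_class", "tier", "metric", "setup_mm")
    )
    stats = compute_run_stats(records, shift_log, class_map, config.setup_mm)

    result = RunResult(
        config=config,
        config_hash=config.config_hash,
        patients=patients,
        bands=bands,
        records=records,
        shift_log=shift_log,
        summaries=summaries,
        stats=stats,
        failures=failures,
    )
    if config.outdir is not None:
        write_outputs(result, config.outdir)
    return result


def write_outputs(result: RunResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = result.config_hash
    pio.write_table(result.bands, outdir / "bands.csv", h)
    pio.write_table(result.records, outdir / "records.csv", h)
    pio.write_table(result.shift_log, outdir / "shifts.csv", h)
    pio.write_table(summaries_to_frame(result.summaries), outdir / "summaries.csv", h)
    (outdir / "summaries.json").write_text(
        json.dumps(
            {"config_hash": h, "summaries": [s.to_dict() for s in result.summaries]},
            indent=2,
        )
    )
    (outdir / "stats.json").write_text(
        json.dumps(
            {"config_hash": h, "tests": [s.to_dict() for s in result.stats]}, indent=2
        )
    )
    (outdir / "metadata.json").write_text(
        json.dumps(
            {
                "config_hash": h,
                "config": result.config.to_dict(),
                "failures": result.failures,
            },
            indent=2,
        )
    )
    if result.config.make_figures:
        from .figures import save_figures

        save_figures(result.bands, result.records, outdir / "figures")
    if result.config.export_grids:
        for p in result.patients:
            doses = [
                compute_dose(p.phantom, p.beams, shift, 1.0) for shift in p.shifts
            ]
            pio.export_cohort_patient(
                outdir, p.id, p.patient_class, p.phantom, p.bands_by_setup, doses, h
            )


# --- externally supplied cohorts -------------------------------------------


def _metrics_from_grid(phantom: Phantom, dose: np.ndarray) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for s in phantom.structures:
        doses = np.asarray(dose)[s.mask]
        if s.is_target:
            out[(s.name, "D95")] = d_at_volume(doses, None, 95.0, name=s.name)
            out[(s.name, "V100")] = v_at_dose(doses, None, float(s.prescription_Gy), name=s.name)
        elif s.metric_kind == "oar_max":
            out[(s.name, "Dmax")] = oar_metric(doses, None, "max", name=s.name)
        else:
            out[(s.name, "Dmean")] = oar_metric(doses, None, "mean", name=s.name)
    return out


def evaluate_imported(
    patients: Sequence[pio.ImportedPatient],
    setup_mm: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Deviation records for externally supplied per-fraction dose grids.

    ``setup_mm`` restricts which band settings are evaluated (default: all
    settings present in the imported band tables).
    """
    all_records: list[DeviationRecord] = []
    for p in patients:
        bands = p.bands_by_setup
        if setup_mm is not None:
            wanted = {float(s) for s in setup_mm}
            bands = {s: b for s, b in bands.items() if s in wanted}
            if not bands:
                raise ConfigurationError(
                    f"patient {p.id!r}: no bands for setups {sorted(wanted)}"
                )
        for i, dose in enumerate(p.fraction_doses):
            metrics = _metrics_from_grid(p.phantom, dose)
            all_records.extend(
                judge_metrics(metrics, p.phantom, bands, patient=p.id, fraction=i)
            )
    return records_to_frame(all_records)
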