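import copy

import numpy as np
import pytest

from protonband.geometry import GridSpec
from protonband.pipeline import RunConfig, run_cohort
from protonband.synthetic.config import default_cohort
from protonband.synthetic.dose import BeamSpec, calibrate_plan
from protonband.synthetic.phantom import build_phantom

DEFAULT_SEED = 1234


@pytest.fixture
def small_grid():
    return GridSpec.centered((20, 20, 24), 2.5)


def tiny_phantom_config():
    """A compact analysis phantom: 2 targets + 3 OARs on a 20x20x24 grid."""
    return {
        "grid": {"shape": [20, 20, 24], "spacing_mm": [2.5, 2.5, 2.5], "origin_mm": None},
        "structures": [
            {
                "name": "primary",
                "role": "primary_target",
                "shape": "ellipsoid",
                "center_mm": [0.0, 0.0, 0.0],
                "radii_mm": [8.0, 8.0, 8.0],
                "prescription_Gy": 60.0,
            },
            {
                "name": "nodes",
                "role": "secondary_target",
                "shape": "capsule",
                "center_mm": [-15.0, 0.0, 0.0],
                "radius_mm": 5.0,
                "half_length_mm": 15.0,
                "axis": "z",
                "prescription_Gy": 54.0,
            },
            {
                "name": "cord",
                "role": "oar",
                "shape": "cylinder",
                "center_mm": [12.0, 8.0, 0.0],
                "radius_mm": 3.0,
                "half_length_mm": 20.0,
                "axis": "z",
                "metric_kind": "oar_max",
            },
            {
                "name": "gland_a",
                "role": "oar",
                "shape": "ellipsoid",
                "center_mm": [14.0, -8.0, 5.0],
                "radii_mm": [4.0, 5.0, 6.0],
                "metric_kind": "oar_mean",
            },
            {
                "name": "gland_b",
                "role": "oar",
                "shape": "box",
                "center_mm": [-12.0, 10.0, -8.0],
                "half_size_mm": [4.0, 4.0, 5.0],
                "metric_kind": "oar_mean",
            },
        ],
    }


@pytest.fixture
def tiny_phantom():
    return build_phantom(tiny_phantom_config())


def tiny_beams():
    common = dict(nominal_range_mm=40.0, modulation_mm=20.0, falloff_sigma_mm=3.0)
    return [
        BeamSpec(direction=(0.0, 1.0, 0.0), isocenter=(0.0, 0.0, 0.0),
                 lateral_sigma_mm=10.0, weight=1.0, **common),
        BeamSpec(direction=(0.0, 1.0, 0.0), isocenter=(-15.0, 0.0, 0.0),
                 lateral_sigma_mm=6.0, weight=0.6, target="nodes", **common),
        BeamSpec(direction=(0.0, 1.0, 0.0), isocenter=(-15.0, 0.0, 9.0),
                 lateral_sigma_mm=6.0, weight=0.6, target="nodes", **common),
        BeamSpec(direction=(0.0, 1.0, 0.0), isocenter=(-15.0, 0.0, -9.0),
                 lateral_sigma_mm=6.0, weight=0.6, target="nodes", **common),
    ]


@pytest.fixture
def tiny_plan(tiny_phantom):
    beams, _ = calibrate_plan(tiny_phantom, tiny_beams())
    return tiny_phantom, beams


def mini_cohort(seed=DEFAULT_SEED, n_fractions=4):
    """Default cohort truncated to one PO and one PNN patient, few fractions."""
    cohort = default_cohort(seed)
    cohort.patients = [cohort.patients[0], cohort.patients[2]]
    for p in cohort.patients:
        p.n_fractions = n_fractions
    return cohort


@pytest.fixture
def mini_run_config(tmp_path):
    return RunConfig(cohort=mini_cohort(), outdir=None, make_figures=False)


@pytest.fixture(scope="session")
def default_run():
    """One full run of the default 6-patient cohort (seed 1234, 203 fractions)."""
    cfg = RunConfig(cohort=default_cohort(DEFAULT_SEED), make_figures=False)
    return run_cohort(cfg)


@pytest.fixture(scope="session")
def default_records_with_class(default_run):
    df = default_run.records.copy()
    df["patient_class"] = df["patient"].map(default_run.class_map)
    return df
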