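import numpy as np
import pytest
from scipy.optimize import brentq

from protonband.dvh import d_at_volume
from protonband.errors import NormalizationError, ValidationError
from protonband.synthetic.dose import (
    BeamSpec,
    calibrate_plan,
    compute_dose,
    depth_dose,
    dose_at_points,
    normalize_plan,
)
from protonband.synthetic.phantom import build_phantom
from protonband.synthetic.shifts import FractionShift

from conftest import tiny_beams, tiny_phantom_config


def simple_beam(**kw):
    defaults = dict(
        direction=(0.0, 1.0, 0.0),
        isocenter=(0.0, 0.0, 0.0),
        nominal_range_mm=50.0,
        modulation_mm=24.0,
        lateral_sigma_mm=12.0,
        falloff_sigma_mm=3.0,
        weight=2.0,
    )
    defaults.update(kw)
    return BeamSpec(**defaults)


def axis_profile_d50(beam, range_scale, step=0.05):
    """Independent oracle: root-find the 50% distal depth on a finely
    sampled on-axis profile."""
    u = np.asarray(beam.direction)
    iso = np.asarray(beam.isocenter)
    mid_depth = beam.nominal_range_mm - 0.5 * beam.modulation_mm

    def dose_at_depth(d):
        point = iso + (d - mid_depth) * u
        return dose_at_points(point[None, :], [beam], None, range_scale)[0]

    peak = beam.weight
    lo = beam.nominal_range_mm * range_scale  # plateau end, dose == peak
    hi = lo + 20 * beam.falloff_sigma_mm
    return brentq(lambda d: dose_at_depth(d) - 0.5 * peak, lo, hi, xtol=1e-10)


class TestBeamSpecValidation:
    def test_non_unit_direction(self):
        with pytest.raises(ValidationError):
            simple_beam(direction=(0.0, 2.0, 0.0))

    def test_direction_tolerance(self):
        simple_beam(direction=(0.0, 1.0 + 5e-10, 0.0))  # within 1e-9

    @pytest.mark.parametrize("kw", [
        {"nominal_range_mm": 10.0, "modulation_mm": 20.0},
        {"modulation_mm": -1.0},
        {"lateral_sigma_mm": 0.0},
        {"falloff_sigma_mm": -2.0},
        {"weight": -0.5},
    ])
    def test_invalid_parameters(self, kw):
        with pytest.raises(ValidationError):
            simple_beam(**kw)


class TestDepthDose:
    def test_plateau_is_exactly_one(self):
        z = depth_dose(np.array([30.0, 40.0, 50.0]), 50.0, 24.0, 3.0)
        np.testing.assert_array_equal(z[1:], [1.0, 1.0])

    def test_zero_before_entry(self):
        assert depth_dose(np.array([-5.0, 0.0]), 50.0, 24.0, 3.0).tolist() == [0.0, 0.0]

    def test_proximal_ramp_below_plateau(self):
        z = depth_dose(np.array([1.0, 13.0, 25.0]), 50.0, 24.0, 3.0)
        assert 0.5 < z[0] < z[1] < z[2] <= 1.0

    def test_distal_monotone_decreasing(self):
        d = np.linspace(50.0, 80.0, 200)
        z = depth_dose(d, 50.0, 24.0, 3.0)
        assert np.all(np.diff(z) <= 0)


class TestComputeDose:
    def test_zero_weights_zero_grid(self, tiny_phantom):
        beams = [simple_beam(weight=0.0)]
        dose = compute_dose(tiny_phantom, beams)
        assert dose.shape == tuple(tiny_phantom.grid.shape)
        assert np.all(dose == 0.0)

    def test_no_beams_zero_grid(self, tiny_phantom):
        assert np.all(compute_dose(tiny_phantom, []) == 0.0)

    def test_mid_plateau_on_axis_closed_form(self):
        """At the isocenter (depth R - M/2, on axis) the dose is exactly the
        beam weight."""
        beam = simple_beam(weight=1.7)
        dose = dose_at_points(np.array([[0.0, 0.0, 0.0]]), [beam])
        assert abs(dose[0] - 1.7) < 1e-9

    def test_point_at_stated_depth(self):
        beam = simple_beam(weight=1.0)
        # depth R - M/2 means y offset 0 by construction; probe another
        # plateau depth explicitly: depth 45 -> y = 45 - (R - M/2) = 7
        dose = dose_at_points(np.array([[0.0, 7.0, 0.0]]), [beam])
        assert abs(dose[0] - 1.0) < 1e-9

    def test_falloff_depth_scales_with_range_scale(self):
        beam = simple_beam()
        d50_nom = axis_profile_d50(beam, 1.0)
        d50_up = axis_profile_d50(beam, 1.035)
        assert abs(d50_up - 1.035 * d50_nom) <= 1.25  # half of a 2.5 mm voxel

    def test_falloff_depth_strictly_increasing_in_range_scale(self):
        beam = simple_beam()
        d50 = [axis_profile_d50(beam, s) for s in (0.965, 1.0, 1.035)]
        assert d50[0] < d50[1] < d50[2]

    def test_linear_in_weights(self, tiny_phantom):
        pts = tiny_phantom.structure_points("primary")
        base = tiny_beams()
        doubled = [BeamSpec(**{**b.__dict__, "weight": 2 * b.weight}) for b in base]
        d1 = dose_at_points(pts, base)
        d2 = dose_at_points(pts, doubled)
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)

    def test_rigid_invariance_under_common_translation(self):
        """Translating anatomy and beams by the same vector leaves the
        masked dose values unchanged."""
        offset = np.array([4.0, -6.0, 10.0])
        cfg = tiny_phantom_config()
        phantom = build_phantom(cfg)
        cfg2 = tiny_phantom_config()
        for s in cfg2["structures"]:
            s["center_mm"] = [c + o for c, o in zip(s["center_mm"], offset)]
        g = cfg2["grid"]
        g["origin_mm"] = [
            -sp * (n - 1) / 2.0 + o
            for n, sp, o in zip(g["shape"], g["spacing_mm"], offset)
        ]
        phantom2 = build_phantom(cfg2)
        beams = tiny_beams()
        beams2 = [
            BeamSpec(**{**b.__dict__, "isocenter": tuple(np.asarray(b.isocenter) + offset)})
            for b in beams
        ]
        for name in ("primary", "nodes", "cord"):
            d1 = dose_at_points(phantom.structure_points(name), beams)
            d2 = dose_at_points(phantom2.structure_points(name), beams2)
            np.testing.assert_allclose(d2, d1, atol=1e-9)

    def test_nominal_recomputation_bit_identical(self, tiny_phantom):
        pts = tiny_phantom.structure_points("primary")
        beams = tiny_beams()
        a = dose_at_points(pts, beams, FractionShift.zero(), 1.0)
        b = dose_at_points(pts, beams, None, 1.0)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("scale", [0.5, 1.3])
    def test_range_scale_bounds(self, tiny_phantom, scale):
        with pytest.raises(ValidationError):
            compute_dose(tiny_phantom, tiny_beams(), None, scale)


class TestNormalization:
    def test_prescription_hit(self, tiny_phantom):
        beams, scale = normalize_plan(tiny_phantom, tiny_beams())
        pts = tiny_phantom.structure_points("primary")
        d95 = d_at_volume(dose_at_points(pts, beams), None, 95.0)
        assert abs(d95 - 60.0) < 0.01
        assert scale > 0

    def test_idempotent(self, tiny_phantom):
        beams, _ = normalize_plan(tiny_phantom, tiny_beams())
        _, scale2 = normalize_plan(tiny_phantom, beams)
        assert abs(scale2 - 1.0) < 1e-6

    def test_scale_invariance(self, tiny_phantom):
        base = tiny_beams()
        doubled = [BeamSpec(**{**b.__dict__, "weight": 2 * b.weight}) for b in base]
        w1 = [b.weight for b in normalize_plan(tiny_phantom, base).beams]
        w2 = [b.weight for b in normalize_plan(tiny_phantom, doubled).beams]
        np.testing.assert_allclose(w1, w2, rtol=1e-12)

    def test_zero_dose_raises(self, tiny_phantom):
        with pytest.raises(NormalizationError):
            normalize_plan(tiny_phantom, [simple_beam(weight=0.0)])

    def test_calibrate_hits_both_prescriptions(self, tiny_phantom):
        beams, _ = calibrate_plan(tiny_phantom, tiny_beams())
        for name, rx in (("primary", 60.0), ("nodes", 54.0)):
            pts = tiny_phantom.structure_points(name)
            d95 = d_at_volume(dose_at_points(pts, beams), None, 95.0)
            assert abs(d95 - rx) < 0.01, name

    def test_calibrate_without_tagged_beams_is_plain_normalization(self, tiny_phantom):
        untagged = [BeamSpec(**{**b.__dict__, "target": None}) for b in tiny_beams()]
        a = calibrate_plan(tiny_phantom, untagged)
        b = normalize_plan(tiny_phantom, untagged)
        np.testing.assert_allclose(
            [x.weight for x in a.beams], [x.weight for x in b.beams], rtol=1e-9
        )
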