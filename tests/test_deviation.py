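import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protonband.bands import ScenarioBand, compute_bands, enumerate_scenarios
from protonband.deviation import (
    evaluate_fraction,
    fractional_dose_deviation,
    fractional_volume_deviation,
    records_to_frame,
    summaries_to_frame,
    summarize,
)
from protonband.errors import ConfigurationError, ValidationError
from protonband.synthetic.shifts import FractionShift


class TestFractionalDoseDeviation:
    def test_inside_band_is_zero(self):
        assert fractional_dose_deviation(60.0, 59.0, 61.0, 60.0) == 0.0

    def test_below_band(self):
        assert fractional_dose_deviation(57.0, 58.0, 62.0, 60.0) == pytest.approx(
            100.0 * 1.0 / 60.0
        )

    def test_above_band(self):
        assert fractional_dose_deviation(63.5, 58.0, 62.0, 60.0) == pytest.approx(2.5)

    def test_on_bound_is_zero(self):
        assert fractional_dose_deviation(58.0, 58.0, 62.0, 60.0) == 0.0
        assert fractional_dose_deviation(62.0, 58.0, 62.0, 60.0) == 0.0

    @pytest.mark.parametrize("rx", [0.0, -10.0])
    def test_nonpositive_prescription(self, rx):
        with pytest.raises(ValidationError):
            fractional_dose_deviation(60.0, 58.0, 62.0, rx)

    def test_inverted_band(self):
        with pytest.raises(ValidationError):
            fractional_dose_deviation(60.0, 62.0, 58.0, 60.0)


class TestFractionalVolumeDeviation:
    def test_below(self):
        assert fractional_volume_deviation(95.0, 96.0, 100.0) == pytest.approx(1.0)

    def test_inside(self):
        assert fractional_volume_deviation(98.0, 96.0, 100.0) == 0.0

    def test_above(self):
        assert fractional_volume_deviation(100.0, 90.0, 99.5) == pytest.approx(0.5)

    @pytest.mark.parametrize("bad", [(-1, 0, 100), (50, -5, 100), (50, 0, 101)])
    def test_out_of_range(self, bad):
        with pytest.raises(ValidationError):
            fractional_volume_deviation(*bad)


@settings(max_examples=200, deadline=None)
@given(
    v=st.floats(0, 100),
    a=st.floats(0, 100),
    b=st.floats(0, 100),
)
def test_zero_iff_inside(v, a, b):
    lo, hi = sorted((a, b))
    dev = fractional_volume_deviation(v, lo, hi)
    if lo <= v <= hi:
        assert dev == 0.0
    else:
        assert dev > 0.0


class TestEvaluateFraction:
    @pytest.fixture
    def bands_by_setup(self, tiny_plan):
        phantom, beams = tiny_plan
        return {
            s: compute_bands(phantom, beams, enumerate_scenarios(s, 0.035), s)
            for s in (3.0, 5.0)
        }

    def test_zero_error_fraction_all_inside(self, tiny_plan, bands_by_setup):
        phantom, beams = tiny_plan
        records = evaluate_fraction(
            phantom, beams, bands_by_setup, FractionShift.zero(), patient="p", fraction=0
        )
        assert records
        for r in records:
            assert str(r.status) == "inside"
            assert r.deviation == 0.0

    def test_record_count(self, tiny_plan, bands_by_setup):
        # 2 targets x (D95 + V100) + 3 OARs = 7 items, x 2 setups = 14 records
        phantom, beams = tiny_plan
        records = evaluate_fraction(phantom, beams, bands_by_setup, FractionShift(tx=1.0))
        assert len(records) == 14

    def test_missing_band_raises(self, tiny_plan, bands_by_setup):
        phantom, beams = tiny_plan
        broken = {3.0: {k: v for k, v in bands_by_setup[3.0].items() if k[0] != "cord"}}
        with pytest.raises(ConfigurationError) as exc:
            evaluate_fraction(phantom, beams, broken, FractionShift.zero())
        assert "cord" in str(exc.value)

    def test_two_mm_lateral_shift_primary_inside_default_phantom(self, default_run):
        patient = default_run.patients[0]
        records = evaluate_fraction(
            patient.phantom,
            patient.beams,
            {3.0: patient.bands_by_setup[3.0]},
            FractionShift(tx=2.0),
        )
        primary = [r for r in records if r.tier == "primary"]
        assert primary
        assert all(str(r.status) == "inside" for r in primary)

    def test_five_mm_deviation_never_exceeds_three_mm(self, default_run):
        """Band nesting implies per-record deviations shrink at 5 mm."""
        df = default_run.records.pivot_table(
            index=["patient", "fraction", "structure", "metric"],
            columns="setup_mm",
            values="deviation",
        )
        assert np.all(df[5.0] <= df[3.0] + 1e-12)


class TestSummarize:
    def _records(self):
        rows = []
        for i in range(10):
            outside = i < 2
            rows.append(
                dict(
                    patient="A" if i < 5 else "B",
                    fraction=i,
                    structure="t",
                    metric="D95",
                    tier="primary",
                    setup_mm=3.0,
                    value=60.0,
                    band_min=59.0,
                    band_max=61.0,
                    status="below" if outside else "inside",
                    deviation=[1.0, 3.0][i] if outside else 0.0,
                )
            )
        return pd.DataFrame(rows)

    def test_two_of_ten_outside(self):
        out = summarize(self._records(), group_by=("setup_mm",))
        assert len(out) == 1
        s = out[0]
        assert s.pct_outside == pytest.approx(20.0)
        assert s.mean_deviation == pytest.approx(2.0)
        assert (s.deviation_min, s.deviation_max) == (1.0, 3.0)
        assert s.mean_deviation_all == pytest.approx(0.4)

    def test_all_inside_reports_zero(self):
        df = self._records()
        df["status"] = "inside"
        df["deviation"] = 0.0
        s = summarize(df, group_by=("setup_mm",))[0]
        assert s.pct_outside == 0.0
        assert s.n_outside == 0
        assert s.mean_deviation == 0.0

    def test_pooled_equals_weighted_combination(self, default_records_with_class):
        """DERIVED: pooled percent-outside equals the record-count-weighted
        combination of the per-class summaries."""
        df = default_records_with_class
        per_class = summarize(df, group_by=("patient_class", "setup_mm"))
        pooled = summarize(df, group_by=("setup_mm",))
        for setup in (3.0, 5.0):
            parts = [s for s in per_class if s.group["setup_mm"] == setup]
            whole = next(s for s in pooled if s.group["setup_mm"] == setup)
            n = sum(p.n_records for p in parts)
            weighted = sum(p.pct_outside * p.n_records for p in parts) / n
            assert whole.pct_outside == pytest.approx(weighted, abs=1e-9)
            assert whole.n_records == n

    def test_class_map_required_and_checked(self):
        with pytest.raises(ConfigurationError):
            summarize(self._records(), group_by=("patient_class",))
        with pytest.raises(ConfigurationError):
            summarize(self._records(), class_map={"A": "PO"}, group_by=("patient_class",))

    def test_empty_records_warn(self):
        with pytest.warns(UserWarning):
            assert summarize(pd.DataFrame()) == []

    def test_frames_round_trip(self, default_run):
        df = summaries_to_frame(default_run.summaries)
        assert {"pct_outside", "mean_deviation", "n_records"} <= set(df.columns)
        assert (df["pct_outside"] >= 0).all() and (df["pct_outside"] <= 100).all()

    def test_records_to_frame_columns(self, default_run):
        assert list(default_run.records.columns) == [
            "patient", "fraction", "structure", "metric", "tier", "setup_mm",
            "value", "band_min", "band_max", "status", "deviation",
        ]
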