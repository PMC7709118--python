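"""MRM quantitation: S/N filtering, ratios, calibration, concentration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assaybridge.mrm import (
    CalibrationError,
    PeptideRatio,
    TransitionRecord,
    calibrate,
    compute_peptide_ratio,
    effective_plasma_concentration,
    quantify,
)


def rec(label, area, bg, sample="s1", protein="APOA4", role="sample"):
    return TransitionRecord(
        sample_id=sample, well_role=role, protein=protein,
        peptide="LEPYADQLR", label=label, total_area=area, total_background=bg,
    )


def passing_ratio(value, sample="s1", protein="APOA4"):
    return PeptideRatio(
        sample_id=sample, protein=protein, light_area=value * 1e6, heavy_area=1e6,
        sn_light=100.0, sn_heavy=100.0, passed_sn=True, ratio=value,
    )


class TestPeptideRatio:
    def test_hand_arithmetic(self):
        r = compute_peptide_ratio([rec("light", 2000, 100), rec("heavy", 1000, 100)])
        assert r.sn_light == 20.0 and r.sn_heavy == 10.0
        assert r.passed_sn and r.ratio == pytest.approx(2.0)

    def test_equal_areas_give_unit_ratio(self):
        r = compute_peptide_ratio([rec("light", 5000, 100), rec("heavy", 5000, 100)])
        assert r.ratio == pytest.approx(1.0)

    def test_sn_below_threshold_blocks_ratio(self):
        # light S/N = 4 fails the > 5 rule even with a clean heavy peak
        r = compute_peptide_ratio([rec("light", 400, 100), rec("heavy", 5000, 100)])
        assert not r.passed_sn and r.ratio is None and not r.missing

    def test_sn_exactly_five_fails_strict_inequality(self):
        r = compute_peptide_ratio([rec("light", 500, 100), rec("heavy", 5000, 100)])
        assert not r.passed_sn

    def test_missing_heavy_flags_missing(self):
        r = compute_peptide_ratio([rec("light", 2000, 100)])
        assert r.missing and not r.passed_sn and r.ratio is None

    def test_zero_background_counts_as_detected(self):
        r = compute_peptide_ratio([rec("light", 2000, 0), rec("heavy", 1000, 100)])
        assert r.passed_sn and r.ratio == pytest.approx(2.0)

    def test_zero_area_zero_background_is_missing(self):
        r = compute_peptide_ratio([rec("light", 0, 0), rec("heavy", 1000, 100)])
        assert r.missing

    def test_transitions_summed_before_ratio(self):
        records = [
            rec("light", 1500, 60), rec("light", 500, 40),
            rec("heavy", 800, 50), rec("heavy", 200, 50),
        ]
        r = compute_peptide_ratio(records)
        assert r.ratio == pytest.approx(2000 / 1000)
        assert r.sn_light == pytest.approx(2000 / 100)


class TestEffectiveConcentration:
    def test_calibrator_volume_ratio(self):
        assert effective_plasma_concentration(18.3, 50, 10) == pytest.approx(91.5)

    def test_equal_volumes_identity(self):
        assert effective_plasma_concentration(7.3, 25, 25) == pytest.approx(7.3)

    def test_low_concentration_calibrator(self):
        # 0.178 µg/mL at 50 vs 10 µL: the formula gives 0.890
        assert effective_plasma_concentration(0.178, 50, 10) == pytest.approx(0.890)

    @pytest.mark.parametrize("v_cal,v_plasma", [(0, 10), (50, 0), (-1, 10)])
    def test_nonpositive_volume_rejected(self, v_cal, v_plasma):
        with pytest.raises(ValueError):
            effective_plasma_concentration(1.0, v_cal, v_plasma)


class TestCalibrate:
    def test_identical_replicates(self):
        rf = calibrate([passing_ratio(2.0) for _ in range(4)], effective_conc=91.5)
        assert rf.mean_calibrator_ratio == pytest.approx(2.0)
        assert rf.replicate_cv == 0.0

    def test_replicate_cv_hand_computed(self):
        rf = calibrate([passing_ratio(v) for v in (1.9, 2.0, 2.1, 2.0)], 91.5)
        assert rf.mean_calibrator_ratio == pytest.approx(2.0)
        assert rf.replicate_cv == pytest.approx(np.std([1.9, 2.0, 2.1, 2.0], ddof=1) / 2.0)
        assert rf.replicate_cv == pytest.approx(0.0408, abs=2e-4)

    def test_sn_failed_replicate_dropped(self):
        failed = PeptideRatio("cal4", "APOA4", 100.0, 1e6, 1.0, 100.0, False, None)
        rf = calibrate([passing_ratio(2.0, f"cal{i}") for i in range(3)] + [failed], 91.5)
        assert rf.n_replicates == 3

    def test_too_few_passing_replicates_aborts(self):
        failed = PeptideRatio("cal2", "APOA4", 100.0, 1e6, 1.0, 100.0, False, None)
        with pytest.raises(CalibrationError):
            calibrate([passing_ratio(2.0), failed], 91.5)

    def test_high_cv_aborts(self):
        with pytest.raises(CalibrationError, match="CV"):
            calibrate([passing_ratio(v) for v in (1.0, 2.0, 3.0, 2.0)], 91.5)


class TestQuantify:
    def rf(self, mean_ratio=1.0, eff=91.5):
        return calibrate([passing_ratio(mean_ratio) for _ in range(4)], eff)

    def test_ratio_at_calibrator_mean_gives_effective_conc(self):
        res = quantify(passing_ratio(1.0), self.rf())
        assert res.concentration == pytest.approx(91.5)

    def test_proportionality(self):
        res = quantify(passing_ratio(0.5), self.rf())
        assert res.concentration == pytest.approx(91.5 / 2)

    def test_above_range_flag(self):
        rf = self.rf()
        res = quantify(passing_ratio(210 / 91.5), rf, working_range=(37.5, 200.0))
        assert res.concentration == pytest.approx(210.0)
        assert res.flags == {"above_range"}

    def test_below_range_reported_with_flag(self):
        res = quantify(passing_ratio(20 / 91.5), self.rf(), working_range=(37.5, 200.0))
        assert res.concentration == pytest.approx(20.0)
        assert res.flags == {"below_lod"}

    def test_sn_fail_gives_no_concentration(self):
        failed = PeptideRatio("s1", "APOA4", 100.0, 1e6, 1.0, 100.0, False, None)
        res = quantify(failed, self.rf())
        assert res.concentration is None and res.flags == {"sn_fail"}

    def test_analyte_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            quantify(passing_ratio(1.0, protein="CD5L"), self.rf())


@settings(deadline=None, max_examples=50)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    cal_ratio=st.floats(min_value=0.2, max_value=5.0),
    sample_ratio=st.floats(min_value=0.2, max_value=5.0),
)
def test_concentration_invariant_to_global_area_scaling(scale, cal_ratio, sample_ratio):
    """Multiplying every area in a batch by a constant changes nothing:
    the light/heavy ratio and the S/N are both area ratios."""
    def run(k):
        cal = []
        for i in range(3):
            r = compute_peptide_ratio(
                [rec("light", k * cal_ratio * 1e6, k * 1e3, sample=f"c{i}"),
                 rec("heavy", k * 1e6, k * 1e3, sample=f"c{i}")]
            )
            cal.append(r)
        rf = calibrate(cal, 91.5)
        sample = compute_peptide_ratio(
            [rec("light", k * sample_ratio * 1e6, k * 1e3), rec("heavy", k * 1e6, k * 1e3)]
        )
        return quantify(sample, rf).concentration

    assert run(scale) == pytest.approx(run(1.0), rel=1e-9)


def test_heavy_normalisation_property():
    """Scaling one sample's light AND heavy areas together is neutral;
    scaling only its light area by k scales its concentration by k."""
    rf = calibrate([passing_ratio(1.0) for _ in range(4)], 91.5)

    def conc(light, heavy):
        r = compute_peptide_ratio([rec("light", light, 100), rec("heavy", heavy, 100)])
        return quantify(r, rf).concentration

    base = conc(2e6, 1e6)
    assert conc(6e6, 3e6) == pytest.approx(base)
    assert conc(2e6 * 3, 1e6) == pytest.approx(base * 3)
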