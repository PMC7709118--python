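"""Synthetic cohort and assay-data generation: determinism, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from assaybridge import elisa, mrm
from assaybridge.config import RunConfig, default_analytes
from assaybridge.synthetic import (
    AnalyteSim,
    CohortSpec,
    IamsBatchLayout,
    elisa_measured_concentrations,
    generate_cohort,
    iams_measured_concentrations,
    simulate_elisa_plate,
    simulate_iams_batch,
    simulate_stability_arms,
    default_curve,
)


def small_spec(n=20, seed=0, **analyte_kw):
    analytes = {
        "APOA4": AnalyteSim(median=110.0, geometric_cv=0.20, bias_mode="additive",
                            bias=-47.93, **analyte_kw),
        "CD5L": AnalyteSim(median=1.6, geometric_cv=0.25, bias_mode="additive",
                           bias=-0.53, **analyte_kw),
        "IBP3": AnalyteSim(median=0.36, geometric_cv=0.25, bias_mode="multiplicative",
                           bias=9.52, **analyte_kw),
    }
    return CohortSpec(n_subjects=n, analytes=analytes, rng_seed=seed)


def noiseless_spec(n=10, seed=0):
    spec = small_spec(n, seed)
    for sim in spec.analytes.values():
        sim.iams_cv = 0.0
        sim.elisa_cv = 0.0
        sim.bias = 0.0 if sim.bias_mode == "additive" else 1.0
    return spec


class TestCohort:
    def test_same_seed_identical_tables(self):
        spec = small_spec(seed=7)
        a = generate_cohort(spec)
        b = generate_cohort(small_spec(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_cohort(small_spec(seed=1))
        b = generate_cohort(small_spec(seed=2))
        assert not a.equals(b)

    def test_geometric_cv_recovered_at_n100(self):
        spec = small_spec(n=100, seed=5)
        truth = generate_cohort(spec)
        for name, sim in spec.analytes.items():
            sample_gcv = float(np.expm1(np.std(np.log(truth[name]), ddof=1)))
            assert sample_gcv == pytest.approx(sim.geometric_cv, rel=0.30)

    def test_medians_near_spec(self):
        spec = small_spec(n=100, seed=5)
        truth = generate_cohort(spec)
        for name, sim in spec.analytes.items():
            assert float(np.median(truth[name])) == pytest.approx(sim.median, rel=0.2)

    def test_concentrations_strictly_positive(self):
        truth = generate_cohort(small_spec(n=100, seed=3))
        assert (truth[["APOA4", "CD5L", "IBP3"]] > 0).all().all()

    def test_single_subject_rejected(self):
        with pytest.raises(Exception, match="n_subjects"):
            small_spec(n=1)

    def test_bad_geometric_cv_rejected(self):
        with pytest.raises(Exception):
            AnalyteSim(median=1.0, geometric_cv=1.5)


class TestIamsBatch:
    def test_noiseless_calibrator_ratio_is_slope_times_effective_conc(self):
        spec = noiseless_spec()
        truth = generate_cohort(spec)
        batch = simulate_iams_batch(
            truth, IamsBatchLayout(), spec, seed=0, heavy_area_cv=0.0
        )
        cal = batch[(batch.sample_id == "CAL_1") & (batch.protein == "APOA4")]
        light = cal[cal.label == "light"].total_area.iloc[0]
        heavy = cal[cal.label == "heavy"].total_area.iloc[0]
        slope = 1.0 / default_analytes()["APOA4"].calibrator_effective_conc
        assert light / heavy == pytest.approx(91.5 * slope, rel=1e-12)

    def test_double_blank_has_no_signal_above_background(self):
        spec = small_spec(n=5)
        batch = simulate_iams_batch(generate_cohort(spec), IamsBatchLayout(), spec, seed=1)
        db = batch[batch.well_role == "double_blank"]
        assert (db.total_area < 5 * db.total_background).all()

    def test_blank_light_fails_sn_filter(self):
        spec = small_spec(n=5)
        batch = simulate_iams_batch(generate_cohort(spec), IamsBatchLayout(), spec, seed=1)
        table, _ = mrm.quantify_batch(batch, RunConfig())
        blanks = table[table.well_role == "blank"]
        assert (blanks.concentration.isna()).all()
        assert blanks["flags"].str.contains("sn_fail").all()

    def test_layout_capacity_enforced(self):
        spec = small_spec(n=90)
        with pytest.raises(ValueError, match="96"):
            simulate_iams_batch(generate_cohort(spec), IamsBatchLayout(), spec, seed=0)

    def test_one_light_one_heavy_per_well_and_peptide(self):
        spec = small_spec(n=5)
        batch = simulate_iams_batch(generate_cohort(spec), IamsBatchLayout(), spec, seed=1)
        counts = batch.groupby(["sample_id", "protein", "label"]).size()
        assert (counts == 1).all()

    def test_quantification_recovers_truth_within_noise(self):
        # full round trip: simulate a batch, quantify, compare with truth;
        # errors should sit within a few times the simulated 5% CV
        spec = small_spec(n=60, seed=9)
        truth = generate_cohort(spec)
        batch = simulate_iams_batch(truth, IamsBatchLayout(), spec, seed=2)
        table, _ = mrm.quantify_batch(batch, RunConfig())
        wide = table[table.well_role == "sample"].pivot(
            index="sample_id", columns="protein", values="concentration"
        )
        for name in spec.analytes:
            rel_err = (wide[name] / truth[name] - 1.0).abs()
            assert rel_err.median() < 3 * 0.05

    def test_deterministic_for_fixed_seed(self):
        spec = small_spec(n=8)
        t = generate_cohort(spec)
        a = simulate_iams_batch(t, IamsBatchLayout(), spec, seed=4)
        b = simulate_iams_batch(t, IamsBatchLayout(), spec, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestElisaPlate:
    def test_seven_standards_on_every_plate(self):
        spec = small_spec(n=6)
        truth = generate_cohort(spec)
        cfg = default_analytes()["APOA4"]
        plate = simulate_elisa_plate(
            truth["APOA4"], "APOA4", default_curve(cfg), cfg.dilution_factor, seed=0
        )
        assert (plate.role == "standard").sum() == 7

    def test_apoa4_assay_concentration_is_plasma_over_400(self):
        spec = noiseless_spec(n=4)
        truth = generate_cohort(spec)
        cfg = default_analytes()["APOA4"]
        curve = default_curve(cfg)
        plate = simulate_elisa_plate(
            truth["APOA4"], "APOA4", curve, cfg.dilution_factor, seed=0, od_noise_sd=0.0
        )
        sample = plate[plate.role == "sample"].iloc[0]
        plasma = truth["APOA4"].loc[sample.well_id]
        expected_od = elisa.four_pl(plasma * 1000 / 400, curve.a, curve.b, curve.c, curve.d)
        assert sample.od450 == pytest.approx(float(expected_od), rel=1e-12)

    def test_zero_noise_round_trip_recovers_truth(self):
        spec = noiseless_spec(n=6)
        truth = generate_cohort(spec)
        for name, cfg in default_analytes().items():
            curve = default_curve(cfg)
            plate = simulate_elisa_plate(
                truth[name], name, curve, cfg.dilution_factor, seed=0, od_noise_sd=0.0
            )
            table, fitted, passed = elisa.quantify_plate(plate, name)
            assert passed
            recovered = table.set_index("sample_id")["concentration"]
            in_range = table[table["flags"] == ""]["sample_id"]
            for sid in in_range:
                assert recovered[sid] == pytest.approx(truth[name].loc[sid], rel=1e-6)


class TestMeasurementChains:
    def test_additive_bias_enters_elisa_readings(self):
        spec = small_spec(n=100, seed=3)
        truth = generate_cohort(spec)
        measured = elisa_measured_concentrations(truth, spec, seed=1)
        diff = truth["APOA4"] - measured["APOA4"]
        assert diff.mean() == pytest.approx(47.93, abs=3 * diff.std() / 10)

    def test_multiplicative_bias_enters_elisa_readings(self):
        spec = small_spec(n=100, seed=3)
        truth = generate_cohort(spec)
        measured = elisa_measured_concentrations(truth, spec, seed=1)
        log_ratio = np.log(measured["IBP3"] / truth["IBP3"])
        assert np.exp(log_ratio.mean()) == pytest.approx(9.52, rel=0.02)

    def test_iams_chain_unbiased(self):
        spec = small_spec(n=100, seed=3)
        truth = generate_cohort(spec)
        measured = iams_measured_concentrations(truth, spec, seed=2)
        assert (measured["CD5L"] / truth["CD5L"]).mean() == pytest.approx(1.0, abs=0.02)


class TestStabilityArms:
    BASE = {"P1": {"APOA4": 110.0}, "P2": {"APOA4": 95.0}, "P3": {"APOA4": 130.0}}

    def test_zero_effect_noiseless_arms_identical(self):
        arms = simulate_stability_arms(
            self.BASE, ["RT_24h"], seed=0, measurement_cv=0.0
        )
        means = arms.groupby("arm").concentration.mean()
        assert means["baseline"] == pytest.approx(means["stressed"])

    def test_design_matches_paired_duplicates_of_three_samples(self):
        arms = simulate_stability_arms(self.BASE, ["4C_24h", "RT_24h"], seed=0)
        counts = arms.groupby(["condition", "arm"]).sample_id.nunique()
        assert (counts == 3).all()
        reps = arms.groupby(["condition", "arm", "sample_id"]).size()
        assert (reps == 2).all()

    def test_injected_degradation_fails_stability(self):
        from assaybridge.validation import stability_compare

        arms = simulate_stability_arms(
            self.BASE, ["freeze_thaw_3x"], effect_model={"freeze_thaw_3x": -0.25},
            seed=1, measurement_cv=0.02,
        )
        verdict = stability_compare(
            arms[arms.arm == "baseline"].concentration,
            arms[arms.arm == "stressed"].concentration,
        )
        assert not verdict.passed
        assert verdict.pct_difference == pytest.approx(-25.0, abs=5.0)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            simulate_stability_arms(self.BASE, ["microwave_5min"], seed=0)

    def test_unknown_effect_model_key_rejected(self):
        with pytest.raises(ValueError, match="effect model"):
            simulate_stability_arms(
                self.BASE, ["RT_24h"], effect_model={"boiled": -0.5}, seed=0
            )
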