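"""Synthetic cohort and assay-data generation with known ground truth.

The study cohort this package targets (100 paired plasma samples measured
on both platforms) is not public, so every input the pipeline consumes is
generated here with known truth: per-subject plasma concentrations and
clinical covariates, transition-level MRM batch tables, ELISA plate
tables, stability arms, dilution series and QC histories.

Simulation model
----------------
* True concentrations are log-normal per analyte (strictly positive and
  right-skewed, like plasma proteins), parameterised by a median (µg/mL)
  and a geometric CV defined as exp(SD(log x)) − 1.
* The MRM response is a light/heavy area ratio linear through the origin
  in plasma-equivalent concentration, with multiplicative log-normal
  noise on the ratio (heavy-area noise cancels in the ratio, as in real
  stable-isotope dilution).
* ELISA readings apply multiplicative measurement noise and the
  configured inter-platform bias at plasma level, then pass through the
  4PL response with additive Gaussian OD noise.
* One seed drives everything; sub-generators get independent streams via
  ``numpy`` seed-sequence spawning, so arms are independent but the whole
  simulation is byte-reproducible.
"""

from __future__ import annotations

from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, PositiveFloat, PositiveInt, model_validator

from .config import AnalyteConfig, default_analytes
from .elisa import StandardCurve, four_pl

KNOWN_STABILITY_CONDITIONS = (
    "4C_24h",
    "RT_24h",
    "freeze_thaw_1x",
    "freeze_thaw_2x",
    "freeze_thaw_3x",
)


class AnalyteSim(BaseModel):
    """Simulation parameters for one analyte."""

    median: PositiveFloat  # true plasma concentration median, µg/mL
    geometric_cv: float = Field(gt=0, lt=1)
    iams_cv: float = Field(default=0.05, ge=0, lt=1)
    elisa_cv: float = Field(default=0.05, ge=0, lt=1)
    bias_mode: Literal["additive", "multiplicative"] = "additive"
    #: additive: µg/mL added to the ELISA reading (negative = ELISA reads low);
    #: multiplicative: factor the ELISA reading is multiplied by.
    bias: float = 0.0

    @model_validator(mode="after")
    def _bias_sane(self) -> "AnalyteSim":
        if self.bias_mode == "multiplicative" and self.bias <= 0:
            raise ValueError("multiplicative bias must be a positive factor")
        return self


class CohortSpec(BaseModel):
    """Specification of the synthetic paired cohort.

    Defaults emulate the published study conditions: 100 subjects, three
    analytes with medians inside both platforms' working ranges, 5%
    per-platform measurement noise, and the inter-platform biases seen in
    the published difference plots (ELISA low by 47.93 µg/mL for APOA4 and
    0.53 µg/mL for CD5L; ELISA high by a factor 9.52 for IBP3).
    """

    n_subjects: PositiveInt = 100
    analytes: dict[str, AnalyteSim] = Field(
        default_factory=lambda: {
            "APOA4": AnalyteSim(median=110.0, geometric_cv=0.20, bias_mode="additive", bias=-47.93),
            "CD5L": AnalyteSim(median=1.6, geometric_cv=0.25, bias_mode="additive", bias=-0.53),
            "IBP3": AnalyteSim(median=0.36, geometric_cv=0.25, bias_mode="multiplicative", bias=9.52),
        }
    )
    age_mean: float = 65.0
    age_sd: PositiveFloat = 9.0
    hdl_median: PositiveFloat = 1.2  # mmol/L
    hdl_geometric_cv: float = Field(default=0.25, gt=0, lt=1)
    egfr_mean: float = 75.0  # mL/min/1.73 m²
    egfr_sd: PositiveFloat = 18.0
    rng_seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "CohortSpec":
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not self.analytes:
            raise ValueError("analytes must not be empty")
        return self


class IamsBatchLayout(BaseModel):
    """Well layout of one 96-well MRM batch."""

    n_calibrator: PositiveInt = 4
    calibrator_volume_ul: PositiveFloat = 50.0
    n_reference: PositiveInt = 4
    reference_volume_ul: PositiveFloat = 10.0
    n_blanks: int = Field(default=2, ge=0)
    n_double_blanks: int = Field(default=1, ge=0)
    sample_volume_ul: PositiveFloat = 10.0
    heavy_spike_fmol: PositiveFloat = 400.0

    def n_control_wells(self) -> int:
        return self.n_calibrator + self.n_reference + self.n_blanks + self.n_double_blanks

    def check_capacity(self, n_samples: int) -> None:
        total = self.n_control_wells() + n_samples
        if total > 96:
            raise ValueError(f"layout needs {total} wells; a plate has 96")


def _sigma(geometric_cv: float) -> float:
    """log-scale SD for a given geometric CV (= exp(sigma) - 1)."""
    return float(np.log1p(geometric_cv))


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators spawned from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the cohort truth table: one row per subject.

    Columns: one true plasma concentration (µg/mL) per analyte plus the
    clinical covariates age (years), hdl (mmol/L) and egfr
    (mL/min/1.73 m²).  Deterministic for a fixed ``spec.rng_seed``.
    """
    rng_conc, rng_cov = _rngs(spec.rng_seed, 2)
    n = spec.n_subjects
    data: dict[str, np.ndarray] = {}
    for name in sorted(spec.analytes):
        sim = spec.analytes[name]
        z = rng_conc.standard_normal(n)
        data[name] = sim.median * np.exp(_sigma(sim.geometric_cv) * z)
    age = np.clip(rng_cov.normal(spec.age_mean, spec.age_sd, n), 30.0, 90.0)
    hdl = spec.hdl_median * np.exp(_sigma(spec.hdl_geometric_cv) * rng_cov.standard_normal(n))
    egfr = np.clip(rng_cov.normal(spec.egfr_mean, spec.egfr_sd, n), 15.0, 120.0)
    idx = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="subject_id")
    return pd.DataFrame({**data, "age": age, "hdl": hdl, "egfr": egfr}, index=idx)


def elisa_measured_concentrations(
    truth: pd.DataFrame, spec: CohortSpec, seed: int
) -> pd.DataFrame:
    """Plasma-level ELISA readings: truth × noise, then the platform bias.

    This is the quantity an ideal (noise-free plate, perfectly fitted
    curve) ELISA would report; :func:`simulate_elisa_plate` pushes it
    through the OD response.  Readings are floored at a vanishing positive
    value so multiplicative downstream analysis never sees zero.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name in sorted(spec.analytes):
        sim = spec.analytes[name]
        reading = truth[name].to_numpy() * np.exp(
            _sigma(sim.elisa_cv) * rng.standard_normal(len(truth))
        )
        if sim.bias_mode == "additive":
            reading = reading + sim.bias
        else:
            reading = reading * sim.bias
        out[name] = np.maximum(reading, 1e-9)
    return pd.DataFrame(out, index=truth.index)


def iams_measured_concentrations(
    truth: pd.DataFrame, spec: CohortSpec, seed: int
) -> pd.DataFrame:
    """Plasma-level MRM readings: truth × per-sample measurement noise.

    The platform-level counterpart of
    :func:`elisa_measured_concentrations` (which additionally applies the
    inter-platform bias).  :func:`simulate_iams_batch` is the full
    transition-level route including calibration; this shortcut carries
    only the per-sample noise and is the reference chain for paired
    bias-recovery studies.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name in sorted(spec.analytes):
        sim = spec.analytes[name]
        out[name] = truth[name].to_numpy() * np.exp(
            _sigma(sim.iams_cv) * rng.standard_normal(len(truth))
        )
    return pd.DataFrame(out, index=truth.index)


def simulate_iams_batch(
    truth: pd.DataFrame,
    layout: IamsBatchLayout,
    spec: CohortSpec,
    seed: int,
    analytes: Optional[Mapping[str, AnalyteConfig]] = None,
    response_slopes: Optional[Mapping[str, float]] = None,
    reference_concs: Optional[Mapping[str, float]] = None,
    heavy_nominal_area: float = 1.0e6,
    heavy_area_cv: float = 0.10,
    background_area: float = 2000.0,
    batch_id: str = "batch1",
) -> pd.DataFrame:
    """Emit one batch's transition-level report as a tidy table.

    Wells: calibrator replicates, reference-plasma replicates, blanks, a
    double blank, and one well per subject.  Each well yields one light
    and one heavy record per analyte peptide.  The light/heavy ratio is
    ``slope × plasma-equivalent concentration`` with multiplicative
    log-normal noise; the default slope (1 / calibrator effective
    concentration) puts calibrator ratios near 1.  Blanks carry light
    signal at background level (S/N ≈ 1, failing the S/N filter); the
    double blank — processed with no antibody beads — additionally has no
    heavy signal above background.
    """
    analytes = dict(analytes) if analytes is not None else default_analytes()
    missing = set(spec.analytes) - set(analytes)
    if missing:
        raise ValueError(f"no analyte registry entries for: {sorted(missing)}")
    layout.check_capacity(len(truth))
    if response_slopes is None:
        response_slopes = {
            name: 1.0 / cfg.calibrator_effective_conc for name, cfg in analytes.items()
        }
    if reference_concs is None:
        reference_concs = {name: spec.analytes[name].median for name in spec.analytes}

    rng = np.random.default_rng(seed)
    names = sorted(spec.analytes)

    wells: list[tuple[str, str, Optional[Mapping[str, float]]]] = []
    for i in range(layout.n_calibrator):
        eff = {
            name: analytes[name].calibrator_solution_conc
            * layout.calibrator_volume_ul
            / layout.sample_volume_ul
            for name in names
        }
        wells.append((f"CAL_{i + 1}", "calibrator", eff))
    for i in range(layout.n_reference):
        wells.append((f"REF_{i + 1}", "reference_plasma", dict(reference_concs)))
    for i in range(layout.n_blanks):
        wells.append((f"BLANK_{i + 1}", "blank", None))
    for i in range(layout.n_double_blanks):
        wells.append((f"DBLANK_{i + 1}", "double_blank", None))
    for subject, row in truth.iterrows():
        wells.append((str(subject), "sample", {name: float(row[name]) for name in names}))

    rows = []
    for sample_id, role, concs in wells:
        for name in names:
            sim = spec.analytes[name]
            peptide = analytes[name].peptide
            if role == "double_blank":
                light = background_area * rng.lognormal(0.0, 0.25)
                heavy = background_area * rng.lognormal(0.0, 0.25)
            else:
                heavy = heavy_nominal_area * (
                    rng.lognormal(0.0, _sigma(heavy_area_cv)) if heavy_area_cv > 0 else 1.0
                )
                if role == "blank":
                    light = background_area * rng.lognormal(0.0, 0.25)
                else:
                    ratio = response_slopes[name] * concs[name]
                    noise = (
                        np.exp(_sigma(sim.iams_cv) * rng.standard_normal())
                        if sim.iams_cv > 0
                        else 1.0
                    )
                    light = ratio * noise * heavy
            for label, area in (("light", light), ("heavy", heavy)):
                rows.append(
                    {
                        "batch_id": batch_id,
                        "sample_id": sample_id,
                        "well_role": role,
                        "protein": name,
                        "peptide": peptide,
                        "label": label,
                        "total_area": float(area),
                        "total_background": background_area,
                    }
                )
    return pd.DataFrame(rows)


def simulate_iams_run(
    truth: pd.DataFrame,
    layout: IamsBatchLayout,
    spec: CohortSpec,
    seed: int,
    analytes: Optional[Mapping[str, AnalyteConfig]] = None,
    **kwargs,
) -> pd.DataFrame:
    """Simulate as many consecutive batches as the cohort needs.

    A 96-well batch holds ``96 - control wells`` samples; larger cohorts
    are split into consecutive batches (batch1, batch2, ...), each with
    its own calibrator and reference wells, exactly as a lab would run
    them.
    """
    capacity = 96 - layout.n_control_wells()
    frames = [
        simulate_iams_batch(
            truth.iloc[i : i + capacity], layout, spec, seed=seed + k,
            analytes=analytes, batch_id=f"batch{k + 1}", **kwargs,
        )
        for k, i in enumerate(range(0, len(truth), capacity))
    ]
    return pd.concat(frames, ignore_index=True)


def default_curve(analyte_cfg: AnalyteConfig) -> StandardCurve:
    """A plausible 4PL response for an analyte's assay range.

    Lower asymptote near blank absorbance, ~1.5 AU span, inflection at the
    geometric middle of the assay working range, slope 1.2.
    """
    lo, hi = analyte_cfg.elisa_assay_range
    return StandardCurve(
        analyte=analyte_cfg.name,
        a=0.05,
        b=1.2,
        c=float(np.sqrt(lo * hi)),
        d=1.60,
        r_squared=1.0,
        working_range=(lo, hi),
    )


def standard_levels(assay_range: tuple[float, float], n: int = 7) -> np.ndarray:
    """Geometric ladder of standard concentrations spanning the assay range."""
    lo, hi = assay_range
    return np.geomspace(lo, hi, n)


def simulate_elisa_plate(
    measured: pd.Series,
    analyte: str,
    curve: StandardCurve,
    dilution: int,
    seed: int,
    od_noise_sd: float = 0.01,
    n_standards: int = 7,
    plate_id: Optional[str] = None,
) -> pd.DataFrame:
    """Emit one analyte's plate table.

    ``measured`` holds the plasma-level concentrations (µg/mL) the plate
    should report for each subject — i.e. truth already carrying the
    platform's noise and bias (see
    :func:`elisa_measured_concentrations`), or raw truth for a noiseless
    round-trip.  Wells: ``n_standards`` standards on a geometric ladder
    across the curve's working range, one low and one high QC, a blank,
    and one well per subject at the analyte's dilution.  OD450 = 4PL of
    the assay-level concentration plus additive Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    plate_id = plate_id or f"{analyte}_plate"
    lo, hi = curve.working_range
    rows = []

    def od_of(assay_conc: float) -> float:
        od = float(four_pl(assay_conc, curve.a, curve.b, curve.c, curve.d))
        if od_noise_sd > 0:
            od += rng.normal(0.0, od_noise_sd)
        return max(od, 0.0)

    for i, level in enumerate(standard_levels((lo, hi), n_standards)):
        rows.append(
            {
                "plate_id": plate_id,
                "well_id": f"STD_{i + 1}",
                "role": "standard",
                "analyte": analyte,
                "dilution_factor": np.nan,
                "od450": od_of(level),
                "nominal_conc": float(level),
            }
        )
    for role, q in (("qc_low", 0.25), ("qc_high", 0.75)):
        nominal = float(lo * (hi / lo) ** q)
        rows.append(
            {
                "plate_id": plate_id,
                "well_id": role.upper(),
                "role": role,
                "analyte": analyte,
                "dilution_factor": np.nan,
                "od450": od_of(nominal),
                "nominal_conc": nominal,
            }
        )
    rows.append(
        {
            "plate_id": plate_id,
            "well_id": "BLANK",
            "role": "blank",
            "analyte": analyte,
            "dilution_factor": np.nan,
            "od450": od_of(0.0),
            "nominal_conc": np.nan,
        }
    )
    for subject, plasma_conc in measured.items():
        assay_conc = float(plasma_conc) * 1000.0 / dilution
        rows.append(
            {
                "plate_id": plate_id,
                "well_id": str(subject),
                "role": "sample",
                "analyte": analyte,
                "dilution_factor": dilution,
                "od450": od_of(assay_conc),
                "nominal_conc": np.nan,
            }
        )
    return pd.DataFrame(rows)


def simulate_stability_arms(
    base_samples: Mapping[str, Mapping[str, float]],
    conditions: Sequence[str],
    effect_model: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    measurement_cv: float = 0.05,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Paired baseline/stressed replicate measurements per condition.

    ``base_samples`` maps plasma sample ids (three independent samples in
    the emulated design) to their true per-analyte concentrations.
    ``effect_model`` gives each condition's fractional concentration shift
    (default 0: analytes are stable).  Output is a tidy table with
    columns condition, arm, sample_id, analyte, replicate, concentration.
    """
    effect_model = dict(effect_model or {})
    unknown = set(conditions) - set(KNOWN_STABILITY_CONDITIONS)
    if unknown:
        raise ValueError(f"unknown stability condition(s): {sorted(unknown)}")
    unknown = set(effect_model) - set(KNOWN_STABILITY_CONDITIONS)
    if unknown:
        raise ValueError(f"effect model names unknown condition(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    sigma = _sigma(measurement_cv) if measurement_cv > 0 else 0.0
    rows = []
    for condition in conditions:
        effect = effect_model.get(condition, 0.0)
        for sample_id, concs in base_samples.items():
            for analyte, true_conc in concs.items():
                for arm, shifted in (("baseline", true_conc), ("stressed", true_conc * (1.0 + effect))):
                    for rep in range(1, n_replicates + 1):
                        noise = np.exp(sigma * rng.standard_normal()) if sigma > 0 else 1.0
                        rows.append(
                            {
                                "condition": condition,
                                "arm": arm,
                                "sample_id": sample_id,
                                "analyte": analyte,
                                "replicate": rep,
                                "concentration": float(shifted * noise),
                            }
                        )
    return pd.DataFrame(rows)


def simulate_dilution_series(
    levels: Sequence[float],
    seed: int,
    cv: float = 0.05,
    n_replicates: int = 3,
) -> dict[float, np.ndarray]:
    """Measured concentrations for a recombinant-protein dilution series."""
    rng = np.random.default_rng(seed)
    sigma = _sigma(cv) if cv > 0 else 0.0
    return {
        float(lv): lv * np.exp(sigma * rng.standard_normal(n_replicates))
        for lv in levels
    }


def simulate_qc_batches(
    reference_concs: Mapping[str, float],
    n_batches: int,
    seed: int,
    cv: float = 0.05,
    batch_cv: float = 0.09,
    n_replicates: int = 4,
) -> list[dict[str, np.ndarray]]:
    """Reference-plasma replicate concentrations for a run of batches.

    Within-batch replicates carry ``cv`` measurement noise; on top of
    that every batch gets a shared multiplicative shift of ``batch_cv``
    per analyte.  The shift bundles everything that moves a whole batch
    together — single-point calibration error, day-to-day instrument
    response, reagent aging — and its default is set so the simulated
    inter-assay CV of batch means lands near the ≈9–11% typical of this
    kind of immunoaffinity MRM assay over months of operation, while the
    within-batch CV stays at the ≈5% replicate level.
    """
    rng = np.random.default_rng(seed)
    sigma = _sigma(cv) if cv > 0 else 0.0
    sigma_b = _sigma(batch_cv) if batch_cv > 0 else 0.0
    batches = []
    for _ in range(n_batches):
        batches.append(
            {
                name: conc
                * (np.exp(sigma_b * rng.standard_normal()) if sigma_b > 0 else 1.0)
                * np.exp(sigma * rng.standard_normal(n_replicates))
                for name, conc in sorted(reference_concs.items())
            }
        )
    return batches
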