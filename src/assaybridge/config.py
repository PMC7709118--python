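"""Run configuration and the default analyte registry.

The three plasma biomarkers of the diabetic-kidney-disease panel — APOA4
(apolipoprotein A-IV), CD5L (CD5 antigen-like) and IBP3 (insulin-like
growth-factor-binding protein 3) — are quantified on two platforms:

* an immunoaffinity MRM mass-spectrometry assay (IAMS) calibrated by a
  single recombinant-protein calibrator and stable-isotope-labelled
  peptides, and
* a sandwich ELISA read at OD450 against a 7-point 4PL standard curve,
  with a per-analyte plasma dilution.

Everything platform-specific that the pipeline needs to know about an
analyte lives in :class:`AnalyteConfig`; a :class:`RunConfig` bundles the
registry with thresholds, seeds and the risk-model coefficients.  All
concentrations are µg/mL at plasma level; ng/mL appears only at the ELISA
assay level (i.e. after dilution).
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, PositiveFloat, PositiveInt, field_validator

BiasMode = Literal["additive", "multiplicative"]

#: Volume of calibrator solution processed per well (µL).
CALIBRATOR_VOLUME_UL = 50.0
#: Volume of plasma processed per well (µL).
PLASMA_VOLUME_UL = 10.0
#: Amount of each heavy (13C/15N) peptide spiked per well (fmol).
HEAVY_SPIKE_FMOL = 400.0


class AnalyteConfig(BaseModel):
    """Registry entry for one biomarker protein."""

    name: str
    peptide: str
    #: Concentration of the analyte in the calibrator *solution* (µg/mL).
    calibrator_solution_conc: PositiveFloat
    #: IAMS plasma working range (µg/mL).
    iams_range: tuple[PositiveFloat, PositiveFloat]
    #: IAMS limit of detection (µg/mL).
    iams_lod: PositiveFloat
    #: ELISA assay-level working range (ng/mL), before the dilution factor.
    elisa_assay_range: tuple[PositiveFloat, PositiveFloat]
    #: Plasma dilution factor for the ELISA ("1 in N").
    dilution_factor: PositiveInt
    #: Bland-Altman bias model used when harmonising ELISA to IAMS.
    bias_mode: BiasMode = "additive"

    @field_validator("iams_range", "elisa_assay_range")
    @classmethod
    def _ordered(cls, v: tuple[float, float]) -> tuple[float, float]:
        if not v[0] < v[1]:
            raise ValueError("range must be (low, high) with low < high")
        return v

    @property
    def calibrator_effective_conc(self) -> float:
        """Plasma-equivalent concentration represented by the calibrator.

        A fixed volume of calibrator solution is processed alongside a
        smaller volume of plasma, so the calibrator "stands for" a plasma
        sample at ``solution concentration × V_cal / V_plasma``.
        """
        return (
            self.calibrator_solution_conc * CALIBRATOR_VOLUME_UL / PLASMA_VOLUME_UL
        )

    @property
    def elisa_plasma_range(self) -> tuple[float, float]:
        """ELISA working range back-converted to plasma µg/mL."""
        lo, hi = self.elisa_assay_range
        f = self.dilution_factor / 1000.0
        return (lo * f, hi * f)


def default_analytes() -> dict[str, AnalyteConfig]:
    """The three-biomarker panel with its published working ranges."""
    return {
        "APOA4": AnalyteConfig(
            name="APOA4",
            peptide="LEPYADQLR",
            calibrator_solution_conc=18.3,
            iams_range=(37.5, 200.0),
            iams_lod=9.40,
            elisa_assay_range=(6.64, 425.0),
            dilution_factor=400,
            bias_mode="additive",
        ),
        "CD5L": AnalyteConfig(
            name="CD5L",
            peptide="LVGGDNLCSGR",
            calibrator_solution_conc=0.686,
            iams_range=(0.104, 10.0),
            iams_lod=0.100,
            elisa_assay_range=(0.16, 10.0),
            dilution_factor=1600,
            bias_mode="additive",
        ),
        "IBP3": AnalyteConfig(
            name="IBP3",
            peptide="FLNVLSPR",
            calibrator_solution_conc=0.178,
            iams_range=(0.0104, 1.00),
            iams_lod=0.010,
            elisa_assay_range=(0.63, 40.0),
            dilution_factor=200,
            bias_mode="multiplicative",
        ),
    }


class RiskModelConfig(BaseModel):
    """Logistic risk-model coefficients.

    The published composite score combines the three biomarkers with age,
    HDL-cholesterol and eGFR through a logistic link and reports the
    probability as a 0–100 score.  The true coefficients are proprietary
    and not public; the defaults below are a synthetic placeholder with
    clinically plausible signs (risk rises with CD5L, IBP3 and age, falls
    with APOA4, HDL and eGFR) and are meant to be overridden from config
    when real coefficients are available.
    """

    intercept: float = -1.5
    apoa4: float = -0.018  # per µg/mL
    cd5l: float = 0.40  # per µg/mL
    ibp3: float = 1.2  # per µg/mL
    age: float = 0.045  # per year
    hdl: float = -0.90  # per mmol/L
    egfr: float = -0.035  # per mL/min/1.73 m²


class QCGateConfig(BaseModel):
    """Parameters of the rolling mean ± k·SD batch-acceptance gate."""

    n_sd: PositiveFloat = 2.0
    min_history: PositiveInt = 5


class RunConfig(BaseModel):
    """Full configuration for a pipeline run."""

    analytes: dict[str, AnalyteConfig] = Field(default_factory=default_analytes)
    sn_threshold: PositiveFloat = 5.0
    calibrator_volume_ul: PositiveFloat = CALIBRATOR_VOLUME_UL
    plasma_volume_ul: PositiveFloat = PLASMA_VOLUME_UL
    qc_gate: QCGateConfig = Field(default_factory=QCGateConfig)
    risk_model: RiskModelConfig = Field(default_factory=RiskModelConfig)
    allowable_score_diff: PositiveFloat = 5.0
    pass_threshold_pct: PositiveFloat = 90.0
    seed: int = 0

    @field_validator("analytes")
    @classmethod
    def _nonempty(cls, v: dict[str, AnalyteConfig]) -> dict[str, AnalyteConfig]:
        if not v:
            raise ValueError("analyte registry must not be empty")
        return v

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
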