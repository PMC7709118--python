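"""Stable-isotope-dilution MRM quantitation from transition-level reports.

The immunoaffinity MRM assay reports, for every (sample, peptide,
transition), an integrated ``Total Area`` and ``Total Background`` for the
endogenous ("light") peptide and its spiked ¹³C/¹⁵N-labelled ("heavy")
counterpart.  Quantitation proceeds in three steps:

1. **S/N filtering and ratioing** — transition areas are summed per
   (peptide, label); a peak passes if area/background > 5 for both light
   and heavy; the light/heavy area ratio normalises instrument response
   (:func:`compute_peptide_ratio`).
2. **Calibration** — the mean light/heavy ratio of the calibrator
   replicates, together with the calibrator's plasma-equivalent
   concentration, defines a per-analyte response factor
   (:func:`calibrate`).
3. **Quantitation** — a sample's concentration is its ratio scaled by the
   response factor (:func:`quantify`), flagged against the plasma working
   range.

Because every well receives the same amount of heavy peptide, the ratio is
invariant to global instrument-response drift, and a single-point
calibrator suffices under a response linear through the origin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalyteConfig, RunConfig

WELL_ROLES = ("calibrator", "reference_plasma", "blank", "double_blank", "sample")


class CalibrationError(RuntimeError):
    """Raised when a batch's calibrator replicates cannot define a response factor."""


@dataclass(frozen=True)
class TransitionRecord:
    """One integrated transition measurement from the exported report."""

    sample_id: str
    well_role: str
    protein: str
    peptide: str
    label: str  # "light" | "heavy"
    total_area: float
    total_background: float

    def __post_init__(self) -> None:
        if self.total_area < 0 or self.total_background < 0:
            raise ValueError("areas and backgrounds must be non-negative")
        if self.label not in ("light", "heavy"):
            raise ValueError(f"label must be 'light' or 'heavy', got {self.label!r}")
        if self.well_role not in WELL_ROLES:
            raise ValueError(f"unknown well role {self.well_role!r}")


@dataclass(frozen=True)
class PeptideRatio:
    """Light/heavy area ratio for one sample × peptide, with S/N bookkeeping."""

    sample_id: str
    protein: str
    light_area: Optional[float]
    heavy_area: Optional[float]
    sn_light: Optional[float]
    sn_heavy: Optional[float]
    passed_sn: bool
    ratio: Optional[float]
    missing: bool = False


@dataclass(frozen=True)
class ResponseFactor:
    """Single-point calibration for one analyte in one batch."""

    protein: str
    calibrator_effective_conc: float  # µg/mL, plasma-equivalent
    mean_calibrator_ratio: float
    replicate_cv: float  # fraction
    n_replicates: int


@dataclass(frozen=True)
class ConcentrationResult:
    """Per-sample per-analyte plasma concentration with QC flags."""

    sample_id: str
    protein: str
    concentration: Optional[float]  # µg/mL; None iff sn_fail or missing
    flags: frozenset[str] = field(default_factory=frozenset)


def effective_plasma_concentration(
    cal_solution_conc: float, v_cal: float, v_plasma: float
) -> float:
    """Plasma-equivalent concentration represented by a calibrator well.

    A calibrator well receives ``v_cal`` µL of solution at
    ``cal_solution_conc`` µg/mL while plasma wells receive ``v_plasma`` µL,
    so the calibrator carries the same analyte mass as a plasma sample at
    ``cal_solution_conc * v_cal / v_plasma`` µg/mL.

    >>> effective_plasma_concentration(18.3, 50, 10)
    91.5
    """
    if v_cal <= 0 or v_plasma <= 0:
        raise ValueError("volumes must be positive")
    return cal_solution_conc * v_cal / v_plasma


def _signal_to_noise(area: float, background: float) -> Optional[float]:
    """area/background; infinite when background is 0 but signal present,
    None when both are 0 (no peak integrated at all)."""
    if background > 0:
        return area / background
    if area > 0:
        return math.inf
    return None


def compute_peptide_ratio(
    records: Iterable[TransitionRecord], sn_threshold: float = 5.0
) -> PeptideRatio:
    """Aggregate the transitions of one sample × peptide into a ratio.

    Multiple transitions per (peptide, label) are summed before ratioing.
    The ratio is only defined when both the light and the heavy summed
    peaks exceed the S/N threshold; a missing light or heavy record yields
    a result flagged ``missing`` rather than an exception.
    """
    records = list(records)
    if not records:
        raise ValueError("no transition records supplied")
    keys = {(r.sample_id, r.protein) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span multiple sample/protein pairs: {keys}")
    sample_id, protein = keys.pop()

    sums: dict[str, tuple[float, float]] = {}
    for label in ("light", "heavy"):
        sub = [r for r in records if r.label == label]
        if sub:
            sums[label] = (
                sum(r.total_area for r in sub),
                sum(r.total_background for r in sub),
            )

    if "light" not in sums or "heavy" not in sums:
        return PeptideRatio(
            sample_id=sample_id,
            protein=protein,
            light_area=sums.get("light", (None,))[0],
            heavy_area=sums.get("heavy", (None,))[0],
            sn_light=None,
            sn_heavy=None,
            passed_sn=False,
            ratio=None,
            missing=True,
        )

    light_area, light_bg = sums["light"]
    heavy_area, heavy_bg = sums["heavy"]
    sn_light = _signal_to_noise(light_area, light_bg)
    sn_heavy = _signal_to_noise(heavy_area, heavy_bg)
    if sn_light is None or sn_heavy is None:
        # a (0, 0) peak means nothing was integrated — treat as missing
        return PeptideRatio(
            sample_id=sample_id,
            protein=protein,
            light_area=light_area,
            heavy_area=heavy_area,
            sn_light=sn_light,
            sn_heavy=sn_heavy,
            passed_sn=False,
            ratio=None,
            missing=True,
        )

    passed = sn_light > sn_threshold and sn_heavy > sn_threshold
    ratio = light_area / heavy_area if passed else None
    return PeptideRatio(
        sample_id=sample_id,
        protein=protein,
        light_area=light_area,
        heavy_area=heavy_area,
        sn_light=sn_light,
        sn_heavy=sn_heavy,
        passed_sn=passed,
        ratio=ratio,
    )


def calibrate(
    calibrator_ratios: Sequence[PeptideRatio],
    effective_conc: float,
    max_cv: float = 0.20,
) -> ResponseFactor:
    """Average the calibrator replicate ratios into a response factor.

    Replicates that failed S/N are dropped; at least two passing replicates
    are required, and a replicate CV at or above ``max_cv`` (default the
    20% ligand-binding precision criterion) fails the calibration, which
    aborts the batch.
    """
    proteins = {r.protein for r in calibrator_ratios}
    if len(proteins) != 1:
        raise ValueError(f"calibrator ratios span multiple proteins: {proteins}")
    protein = proteins.pop()
    passing = [r.ratio for r in calibrator_ratios if r.passed_sn and r.ratio is not None]
    if len(passing) < 2:
        raise CalibrationError(
            f"{protein}: only {len(passing)} calibrator replicate(s) passed S/N; "
            "need at least 2"
        )
    mean = float(np.mean(passing))
    sd = float(np.std(passing, ddof=1))
    cv = sd / mean
    if cv >= max_cv:
        raise CalibrationError(
            f"{protein}: calibrator replicate CV {cv:.1%} >= {max_cv:.0%}"
        )
    return ResponseFactor(
        protein=protein,
        calibrator_effective_conc=effective_conc,
        mean_calibrator_ratio=mean,
        replicate_cv=cv,
        n_replicates=len(passing),
    )


def quantify(
    ratio: PeptideRatio,
    rf: ResponseFactor,
    working_range: Optional[tuple[float, float]] = None,
) -> ConcentrationResult:
    """Convert a sample's light/heavy ratio into a plasma concentration.

    concentration = calibrator effective concentration × ratio / mean
    calibrator ratio.  Results outside the plasma working range are
    reported (not censored) with a ``below_lod`` or ``above_range`` flag so
    that downstream method-agreement analysis keeps its pairs.
    """
    if ratio.protein != rf.protein:
        raise ValueError(
            f"analyte mismatch: ratio is {ratio.protein}, response factor is {rf.protein}"
        )
    flags: set[str] = set()
    if ratio.missing:
        return ConcentrationResult(ratio.sample_id, ratio.protein, None, frozenset({"missing"}))
    if not ratio.passed_sn:
        return ConcentrationResult(ratio.sample_id, ratio.protein, None, frozenset({"sn_fail"}))
    conc = rf.calibrator_effective_conc * ratio.ratio / rf.mean_calibrator_ratio
    if working_range is not None:
        lo, hi = working_range
        if conc < lo:
            flags.add("below_lod")
        elif conc > hi:
            flags.add("above_range")
    return ConcentrationResult(ratio.sample_id, ratio.protein, conc, frozenset(flags))


def ratios_from_report(
    report: pd.DataFrame, sn_threshold: float = 5.0
) -> list[PeptideRatio]:
    """Group a canonical transition report into per-(sample, protein) ratios."""
    required = {"sample_id", "well_role", "protein", "peptide", "label",
                "total_area", "total_background"}
    missing = required - set(report.columns)
    if missing:
        raise ValueError(f"transition report missing columns: {sorted(missing)}")
    out: list[PeptideRatio] = []
    for (_, _), group in report.groupby(["sample_id", "protein"], sort=False):
        records = [
            TransitionRecord(
                sample_id=row.sample_id,
                well_role=row.well_role,
                protein=row.protein,
                peptide=row.peptide,
                label=row.label,
                total_area=float(row.total_area),
                total_background=float(row.total_background),
            )
            for row in group.itertuples()
        ]
        out.append(compute_peptide_ratio(records, sn_threshold=sn_threshold))
    return out


def quantify_batch(
    report: pd.DataFrame, config: Optional[RunConfig] = None
) -> tuple[pd.DataFrame, dict[str, ResponseFactor]]:
    """Quantify one IAMS batch end to end.

    Returns a tidy concentration table (one row per well × analyte, with
    the well role carried through) and the per-analyte response factors.
    Calibrator wells define the response factors; every other well —
    reference plasma, blanks, unknowns — is quantified against them.
    Blank wells with apparent concentration above the analyte LOD trigger a
    warning, since carry-over there would bias low-end samples.
    """
    config = config or RunConfig()
    roles = report.set_index("sample_id")["well_role"].to_dict()
    ratios = ratios_from_report(report, sn_threshold=config.sn_threshold)

    factors: dict[str, ResponseFactor] = {}
    for name, analyte in config.analytes.items():
        cal = [r for r in ratios if r.protein == name and roles.get(r.sample_id) == "calibrator"]
        if not cal:
            raise CalibrationError(f"{name}: no calibrator wells in batch")
        eff = effective_plasma_concentration(
            analyte.calibrator_solution_conc,
            config.calibrator_volume_ul,
            config.plasma_volume_ul,
        )
        factors[name] = calibrate(cal, eff)

    rows = []
    for r in ratios:
        if r.protein not in factors:
            continue
        role = roles.get(r.sample_id, "sample")
        analyte = config.analytes[r.protein]
        res = quantify(r, factors[r.protein], working_range=analyte.iams_range)
        if role == "blank" and res.concentration is not None:
            if res.concentration > analyte.iams_lod:
                warnings.warn(
                    f"blank well {r.sample_id} shows apparent {r.protein} "
                    f"{res.concentration:.3g} µg/mL above LOD {analyte.iams_lod:g}",
                    stacklevel=2,
                )
        rows.append(
            {
                "sample_id": res.sample_id,
                "well_role": role,
                "protein": res.protein,
                "concentration": res.concentration,
                "flags": ";".join(sorted(res.flags)),
            }
        )
    table = pd.DataFrame(rows, columns=["sample_id", "well_role", "protein", "concentration", "flags"])
    return table, factors
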