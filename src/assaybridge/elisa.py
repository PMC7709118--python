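"""Four-parameter-logistic ELISA quantitation.

Each biomarker plate carries a 7-point standard curve of recombinant
protein, low/high QC wells and one well per plasma sample at the
analyte's dilution.  OD450 readings follow the 4PL model

    OD(x) = d + (a - d) / (1 + (x / c)^b)

with ``a`` the zero-concentration (lower) asymptote, ``d`` the saturating
(upper) asymptote, ``c`` the inflection concentration (ng/mL) and ``b``
the slope.  The curve is fitted per plate by unweighted least squares and
inverted in closed form; plasma concentrations are assay concentrations
times the dilution factor (ng/mL → µg/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .mrm import ConcentrationResult

WELL_ROLES = ("standard", "qc_low", "qc_high", "sample", "blank")


class CurveFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlateWell:
    plate_id: str
    well_id: str
    role: str
    analyte: str
    od450: float
    dilution_factor: Optional[int] = None  # samples
    nominal_conc: Optional[float] = None  # ng/mL; standards and QCs

    def __post_init__(self) -> None:
        if self.role not in WELL_ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if self.od450 < 0:
            raise ValueError("OD450 must be non-negative")
        if self.role == "standard" and self.nominal_conc is None:
            raise ValueError("standard wells need a nominal concentration")
        if self.role == "sample" and self.dilution_factor is None:
            raise ValueError("sample wells need a dilution factor")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted 4PL parameters and goodness of fit for one analyte/plate."""

    analyte: str
    a: float  # lower asymptote (OD)
    b: float  # slope
    c: float  # inflection concentration (ng/mL)
    d: float  # upper asymptote (OD)
    r_squared: float
    working_range: tuple[float, float]  # ng/mL, span of the standards


def four_pl(x, a: float, b: float, c: float, d: float):
    """4PL response: OD at assay concentration ``x`` (ng/mL)."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


def fit_4pl(
    standards: Sequence[tuple[float, float]], analyte: str = ""
) -> StandardCurve:
    """Fit a 4PL standard curve to (nominal ng/mL, OD450) pairs.

    Requires at least five distinct concentration levels.  Initial values
    follow the usual sigmoid heuristic: asymptotes at the observed OD
    extremes, inflection at the geometric mean of the standards, unit
    slope.  Non-convergence raises :class:`CurveFitError` naming the
    analyte.
    """
    conc = np.asarray([s[0] for s in standards], dtype=float)
    od = np.asarray([s[1] for s in standards], dtype=float)
    if len(np.unique(conc)) < 5:
        raise ValueError("need at least 5 distinct standard levels for a 4PL fit")
    if not (np.isfinite(od).all() and np.isfinite(conc).all()):
        raise ValueError("standards contain non-finite values")
    if (conc <= 0).any():
        raise ValueError("standard concentrations must be positive")

    p0 = [od.min(), 1.0, float(np.exp(np.mean(np.log(conc)))), od.max()]
    try:
        popt, _ = curve_fit(four_pl, conc, od, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise CurveFitError(f"4PL fit failed for {analyte or 'analyte'}: {exc}") from exc
    a, b, c, d = (float(v) for v in popt)
    if c <= 0:
        raise CurveFitError(f"4PL fit for {analyte or 'analyte'} gave non-positive inflection")
    resid = od - four_pl(conc, a, b, c, d)
    ss_tot = float(np.sum((od - od.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return StandardCurve(
        analyte=analyte,
        a=a,
        b=b,
        c=c,
        d=d,
        r_squared=r2,
        working_range=(float(conc.min()), float(conc.max())),
    )


def invert_4pl(curve: StandardCurve, od450: float) -> Optional[float]:
    """Closed-form inverse of the 4PL: assay concentration for an OD.

    Returns None when the OD lies outside the open interval between the
    asymptotes, where the curve carries no concentration information.
    """
    lo, hi = sorted((curve.a, curve.d))
    if not (lo < od450 < hi):
        return None
    ratio = (curve.a - curve.d) / (od450 - curve.d) - 1.0
    return float(curve.c * ratio ** (1.0 / curve.b))


def quantify_well(curve: StandardCurve, well: PlateWell) -> ConcentrationResult:
    """Plasma concentration (µg/mL) for a sample well.

    plasma µg/mL = assay ng/mL × dilution factor / 1000.  ODs outside the
    curve's asymptotes yield a flagged result with no value; assay
    concentrations outside the standards' span are flagged but reported.
    """
    if well.role != "sample":
        raise ValueError(f"quantify_well expects a sample well, got role {well.role!r}")
    assay = invert_4pl(curve, well.od450)
    if assay is None:
        # saturated toward the zero-concentration asymptote reads as below
        # detection, toward the upper asymptote as above range
        side = "below_lod" if abs(well.od450 - curve.a) <= abs(well.od450 - curve.d) else "above_range"
        return ConcentrationResult(
            well.well_id, curve.analyte, None, frozenset({side, "missing"})
        )
    flags: set[str] = set()
    lo, hi = curve.working_range
    if assay < lo:
        flags.add("below_lod")
    elif assay > hi:
        flags.add("above_range")
    plasma = assay * well.dilution_factor / 1000.0
    return ConcentrationResult(well.well_id, curve.analyte, plasma, frozenset(flags))


def check_plate_qc(
    curve: StandardCurve, qc_wells: Sequence[PlateWell], tolerance: float = 0.20
) -> tuple[bool, pd.DataFrame]:
    """Back-calculate the QC wells and gate the plate.

    The plate passes iff every QC well's back-calculated concentration is
    within ``tolerance`` (default ±20%, the ligand-binding accuracy
    criterion) of its nominal.  Returns (passed, per-well detail).
    """
    qcs = [w for w in qc_wells if w.role in ("qc_low", "qc_high")]
    roles = {w.role for w in qcs}
    if "qc_low" not in roles or "qc_high" not in roles:
        raise ValueError("plate QC needs at least one low and one high QC well")
    rows = []
    for w in qcs:
        if w.nominal_conc is None:
            raise ValueError(f"QC well {w.well_id} has no nominal concentration")
        back = invert_4pl(curve, w.od450)
        recovery = back / w.nominal_conc if back is not None else np.nan
        ok = back is not None and abs(recovery - 1.0) <= tolerance
        rows.append(
            {
                "well_id": w.well_id,
                "role": w.role,
                "nominal_conc": w.nominal_conc,
                "back_calculated": back,
                "recovery": recovery,
                "pass": ok,
            }
        )
    detail = pd.DataFrame(rows)
    return bool(detail["pass"].all()), detail


def quantify_plate(
    plate: pd.DataFrame, analyte: str, qc_tolerance: float = 0.20
) -> tuple[pd.DataFrame, StandardCurve, bool]:
    """Fit, QC-check and quantify one plate table.

    The plate table uses the canonical columns (plate_id, well_id, role,
    analyte, dilution_factor, od450, nominal_conc).  Returns the sample
    concentration table, the fitted curve, and the plate QC verdict.
    """
    sub = plate[plate["analyte"] == analyte]
    if sub.empty:
        raise ValueError(f"plate contains no wells for analyte {analyte!r}")
    std = sub[sub["role"] == "standard"]
    curve = fit_4pl(
        list(zip(std["nominal_conc"].astype(float), std["od450"].astype(float))),
        analyte=analyte,
    )
    qc_wells = [_well_from_row(r) for r in sub[sub["role"].isin(["qc_low", "qc_high"])].itertuples()]
    passed, _ = check_plate_qc(curve, qc_wells, tolerance=qc_tolerance)
    rows = []
    for r in sub[sub["role"] == "sample"].itertuples():
        res = quantify_well(curve, _well_from_row(r))
        rows.append(
            {
                "sample_id": res.sample_id,
                "protein": analyte,
                "concentration": res.concentration,
                "flags": ";".join(sorted(res.flags)),
            }
        )
    table = pd.DataFrame(rows, columns=["sample_id", "protein", "concentration", "flags"])
    return table, curve, passed


def _well_from_row(row) -> PlateWell:
    dil = getattr(row, "dilution_factor", None)
    nom = getattr(row, "nominal_conc", None)
    return PlateWell(
        plate_id=str(row.plate_id),
        well_id=str(row.well_id),
        role=str(row.role),
        analyte=str(row.analyte),
        od450=float(row.od450),
        dilution_factor=int(dil) if dil is not None and not pd.isna(dil) else None,
        nominal_conc=float(nom) if nom is not None and not pd.isna(nom) else None,
    )
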