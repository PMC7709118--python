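"""Assay characterisation: linearity, LOD/LOQ, precision and stability.

Verdicts follow the ligand-binding acceptance convention used throughout
the package: accuracy within 20% of nominal and precision CV below 20%.
All CVs are sample CVs (SD with one delta degree of freedom over the
mean) reported as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class LinearityResult:
    r_squared: float
    slope: float
    intercept: float
    #: per-level mean recovery (%) and replicate CV (%), indexed by nominal
    per_level: pd.DataFrame


@dataclass(frozen=True)
class LodLoqResult:
    lod: Optional[float]  # None = above tested range
    loq: Optional[float]
    lod_rule: str
    loq_rule: str


@dataclass(frozen=True)
class PrecisionResult:
    intra_cv_pct: float  # mean of within-batch CVs
    inter_cv_pct: Optional[float]  # CV of batch means; None for a single batch
    n_batches: int


@dataclass(frozen=True)
class StabilityVerdict:
    pct_difference: float
    baseline_cv_pct: float
    stressed_cv_pct: float
    passed: bool


@dataclass(frozen=True)
class ValidationReport:
    """Collected characterisation results for one analyte."""

    analyte: str
    linearity: Optional[LinearityResult] = None
    lod_loq: Optional[LodLoqResult] = None
    precision: Optional[PrecisionResult] = None
    stability: dict[str, StabilityVerdict] = field(default_factory=dict)


def _cv_pct(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m == 0:
        raise ValueError("mean is zero; CV undefined")
    if len(x) < 2:
        return 0.0
    return float(100.0 * x.std(ddof=1) / m)


def linearity(series: Mapping[float, Sequence[float]]) -> LinearityResult:
    """Ordinary least-squares fit of measured on nominal concentration.

    ``series`` maps each nominal level to its replicate measured
    concentrations; at least five levels with two replicates each are
    required.  Per-level recovery (mean measured / nominal, %) and
    replicate CV accompany the global R² and slope.
    """
    levels = sorted(series)
    if len(levels) < 5:
        raise ValueError(f"linearity needs >= 5 levels, got {len(levels)}")
    for lv in levels:
        if len(series[lv]) < 2:
            raise ValueError(f"level {lv} has fewer than 2 replicates")
    nominal = np.concatenate([[lv] * len(series[lv]) for lv in levels])
    measured = np.concatenate([np.asarray(series[lv], dtype=float) for lv in levels])
    fit = stats.linregress(nominal, measured)
    per_level = pd.DataFrame(
        {
            "nominal": levels,
            "mean_measured": [float(np.mean(series[lv])) for lv in levels],
            "recovery_pct": [100.0 * float(np.mean(series[lv])) / lv for lv in levels],
            "cv_pct": [_cv_pct(np.asarray(series[lv], dtype=float)) for lv in levels],
        }
    ).set_index("nominal")
    return LinearityResult(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        per_level=per_level,
    )


def estimate_lod_loq(
    series: Mapping[float, Sequence[float]],
    blanks: Optional[Sequence[float]] = None,
    detected: Optional[Mapping[float, Sequence[bool]]] = None,
    accuracy_tol: float = 0.20,
    cv_limit: float = 0.20,
) -> LodLoqResult:
    """Empirical LOD and LOQ from a dilution series.

    Detection at a level means every replicate is individually
    distinguishable from blank: either an explicit per-replicate
    ``detected`` indicator (e.g. the S/N > 5 pass flag of the MS assay) or,
    when blank readings are supplied, signal above mean(blank) + 3·SD.
    LOD is the lowest fully detected level.  LOQ additionally requires
    quantitative reliability: mean recovery within ``accuracy_tol`` of
    nominal and replicate CV below ``cv_limit``.  Levels above the tested
    range are reported as None.
    """
    if blanks is None and detected is None:
        raise ValueError("need either blank measurements or a detection indicator")
    if detected is None:
        b = np.asarray(blanks, dtype=float)
        threshold = b.mean() + 3.0 * b.std(ddof=1)
        lod_rule = f"all replicates > mean(blank) + 3 SD ({threshold:.4g})"
        detected = {
            lv: [float(v) > threshold for v in vals] for lv, vals in series.items()
        }
    else:
        lod_rule = "all replicates pass the detection criterion (S/N > threshold)"
    loq_rule = (
        f"lowest level with |recovery - 100%| <= {accuracy_tol:.0%} "
        f"and CV < {cv_limit:.0%}"
    )

    lod = None
    for lv in sorted(series):
        flags = detected.get(lv, [])
        if flags and all(flags):
            lod = float(lv)
            break

    loq = None
    for lv in sorted(series):
        vals = np.asarray(series[lv], dtype=float)
        flags = detected.get(lv, [])
        if not (flags and all(flags)):
            continue
        recovery = vals.mean() / lv
        cv = _cv_pct(vals) / 100.0
        if abs(recovery - 1.0) <= accuracy_tol and cv < cv_limit:
            loq = float(lv)
            break
    return LodLoqResult(lod=lod, loq=loq, lod_rule=lod_rule, loq_rule=loq_rule)


def precision(batches: Sequence[Sequence[float]]) -> PrecisionResult:
    """Intra- and inter-assay precision from replicate batches.

    Intra-assay CV is the average of the within-batch CVs ("average % CV");
    inter-assay CV is the CV of the batch means.  A single batch yields no
    inter-assay estimate.
    """
    if not batches:
        raise ValueError("no batches supplied")
    arrays = [np.asarray(b, dtype=float) for b in batches]
    for i, b in enumerate(arrays):
        if len(b) < 2:
            raise ValueError(f"batch {i} has fewer than 2 replicates")
    intra = float(np.mean([_cv_pct(b) for b in arrays]))
    if len(arrays) >= 2:
        means = np.array([b.mean() for b in arrays])
        inter = _cv_pct(means)
    else:
        inter = None
    return PrecisionResult(intra_cv_pct=intra, inter_cv_pct=inter, n_batches=len(arrays))


def stability_compare(
    baseline: Sequence[float],
    stressed: Sequence[float],
    max_pct_difference: float = 20.0,
    max_cv_pct: float = 20.0,
) -> StabilityVerdict:
    """Compare a stressed replicate arm against its paired baseline arm.

    %difference = 100 × (stressed mean − baseline mean) / baseline mean.
    The condition passes iff |%difference| is within the accuracy criterion
    and both arms' CVs are below the precision criterion.
    """
    base = np.asarray(baseline, dtype=float)
    stress = np.asarray(stressed, dtype=float)
    if len(base) < 2 or len(stress) < 2:
        raise ValueError("both arms need at least 2 replicates")
    if base.mean() == 0:
        raise ValueError("baseline mean is zero; %difference undefined")
    pct_diff = float(100.0 * (stress.mean() - base.mean()) / base.mean())
    cv_b = _cv_pct(base)
    cv_s = _cv_pct(stress)
    passed = bool(abs(pct_diff) <= max_pct_difference and cv_b < max_cv_pct and cv_s < max_cv_pct)
    return StabilityVerdict(
        pct_difference=pct_diff,
        baseline_cv_pct=cv_b,
        stressed_cv_pct=cv_s,
        passed=passed,
    )


def freeze_thaw_average_cv(cycle_series: Mapping[str, Sequence[float]]) -> float:
    """Average CV across repeated freeze-thaw cycles.

    ``cycle_series`` maps each plasma sample to its measured concentration
    at successive cycle counts (0×, 1×, 2×, 3×).  Each sample contributes
    the CV across its cycle measurements; the average over samples is the
    summary figure used to report freeze-thaw robustness.
    """
    if not cycle_series:
        raise ValueError("no samples supplied")
    cvs = []
    for sample, vals in cycle_series.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 2:
            raise ValueError(f"sample {sample} has fewer than 2 cycle measurements")
        cvs.append(_cv_pct(v))
    return float(np.mean(cvs))
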