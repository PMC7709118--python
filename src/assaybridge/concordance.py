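"""Cross-platform harmonisation and risk-score concordance.

The two platforms measure the same plasma samples, but an immunoassay's
absolute scale depends on its antibodies and calibrants, so paired
concentrations typically show a systematic bias.  Bland-Altman analysis
estimates that bias from the distribution of paired differences — on the
raw scale when the offset is constant (additive mode), on the log scale
when the platforms differ by a constant factor (multiplicative mode) —
and the ELISA values are then adjusted onto the MS scale before composite
risk scores are compared.

Sign conventions (chosen so the reported value *is* the correction applied
to the ELISA):

* additive bias  = mean(IAMS − ELISA); adjusted = ELISA + bias
* multiplicative factor = geometric mean(ELISA / IAMS); adjusted = ELISA / factor

Concordance of the composite score is summarised by the Pearson
correlation of paired scores and the fraction of subjects whose scores
agree within an allowable difference (default 5 points on the 0–100
scale), with the cohort passing when that fraction exceeds 90%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .config import BiasMode, RiskModelConfig


@dataclass(frozen=True)
class BlandAltmanResult:
    analyte: str
    mode: BiasMode
    #: additive: µg/mL added to ELISA; multiplicative: dimensionless divisor
    bias: float
    #: SD of the paired differences (log-scale differences in multiplicative mode)
    sd_diff: float
    #: bias ± 1.96·SD, back-transformed to a factor in multiplicative mode
    loa_lower: float
    loa_upper: float
    t_statistic: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ConcordanceSummary:
    r: float  # Pearson correlation of paired scores (nan if degenerate)
    abs_differences: np.ndarray
    fraction_within: float
    allowable_diff: float
    pass_threshold_pct: float
    passed: bool


def bland_altman(
    iams: Sequence[float],
    elisa: Sequence[float],
    mode: BiasMode = "additive",
    analyte: str = "",
) -> BlandAltmanResult:
    """Estimate the inter-platform bias from paired measurements.

    Additive mode works on differences d = IAMS − ELISA: bias = mean(d),
    limits of agreement bias ± 1.96·SD(d).  Multiplicative mode works on
    log(ELISA) − log(IAMS): the reported bias is the geometric mean ratio
    ELISA/IAMS (the divisor later applied to the ELISA values) and the
    limits of agreement are back-transformed to factors.  A one-sample
    two-sided t-test assesses mean difference = 0 (t = mean/(SD/√n),
    df = n − 1); with SD = 0 the test degenerates to t = 0, p = 1 for
    identical pairs and t = ±inf, p = 0 for a nonzero constant offset.
    """
    a = np.asarray(iams, dtype=float)
    b = np.asarray(elisa, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired measurement arrays differ in length")
    n = len(a)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")

    if mode == "additive":
        d = a - b
    elif mode == "multiplicative":
        bad = np.flatnonzero((a <= 0) | (b <= 0))
        if bad.size:
            raise ValueError(
                "multiplicative mode requires strictly positive values; "
                f"offending pair indices: {bad.tolist()}"
            )
        d = np.log(b) - np.log(a)  # log of the ELISA/IAMS ratio
    else:
        raise ValueError(f"unknown bias mode {mode!r}")

    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean_d == 0.0 else float(np.sign(mean_d)) * float("inf")
        p = 1.0 if mean_d == 0.0 else 0.0
    else:
        t = mean_d / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))

    if mode == "additive":
        bias, lo, hi = mean_d, mean_d - 1.96 * sd, mean_d + 1.96 * sd
    else:
        bias = float(np.exp(mean_d))
        lo = float(np.exp(mean_d - 1.96 * sd))
        hi = float(np.exp(mean_d + 1.96 * sd))
    return BlandAltmanResult(
        analyte=analyte,
        mode=mode,
        bias=bias,
        sd_diff=sd,
        loa_lower=lo,
        loa_upper=hi,
        t_statistic=float(t),
        p_value=p,
        n=n,
    )


def apply_adjustment(
    elisa: Sequence[float], ba: BlandAltmanResult, analyte: Optional[str] = None
) -> np.ndarray:
    """Move ELISA concentrations onto the MS scale.

    Additive: adjusted = ELISA + bias.  Multiplicative: adjusted =
    ELISA / bias factor.  After adjustment the mean (log-mean) paired
    difference against the IAMS values used to fit ``ba`` is zero to
    numerical tolerance.
    """
    if analyte is not None and ba.analyte and analyte != ba.analyte:
        raise ValueError(f"adjustment for {ba.analyte} applied to {analyte}")
    vals = np.asarray(elisa, dtype=float)
    if ba.mode == "additive":
        return vals + ba.bias
    return vals / ba.bias


def bias_mode_diagnostic(
    iams: Sequence[float], elisa: Sequence[float]
) -> dict[str, float]:
    """Correlation of the paired difference with the pair mean.

    A strong positive correlation indicates the offset grows with
    concentration — evidence for a multiplicative rather than additive
    bias model.  Reported for the analyst; the configured mode is never
    switched automatically.
    """
    a = np.asarray(iams, dtype=float)
    b = np.asarray(elisa, dtype=float)
    diff = a - b
    mean = (a + b) / 2.0
    if np.std(diff) == 0 or np.std(mean) == 0:
        return {"r_diff_vs_mean": float("nan"), "p_value": float("nan")}
    r, p = stats.pearsonr(diff, mean)
    return {"r_diff_vs_mean": float(r), "p_value": float(p)}


def risk_score(
    apoa4: float,
    cd5l: float,
    ibp3: float,
    age: float,
    hdl: float,
    egfr: float,
    model: Optional[RiskModelConfig] = None,
) -> float:
    """Composite 0–100 risk score from the biomarker panel and covariates.

    score = 100 × logistic(intercept + Σ coefficient × input).  All six
    inputs are required and must be finite.
    """
    model = model or RiskModelConfig()
    inputs = {"apoa4": apoa4, "cd5l": cd5l, "ibp3": ibp3, "age": age, "hdl": hdl, "egfr": egfr}
    for name, value in inputs.items():
        if value is None or not np.isfinite(value):
            raise ValueError(f"risk score input {name!r} is missing or non-finite")
    lp = model.intercept + sum(getattr(model, k) * v for k, v in inputs.items())
    return float(100.0 * expit(lp))


def risk_scores_table(
    concentrations: pd.DataFrame,
    manifest: pd.DataFrame,
    model: Optional[RiskModelConfig] = None,
) -> pd.Series:
    """Score every subject from a wide concentration table plus covariates.

    ``concentrations`` must carry columns APOA4, CD5L, IBP3 indexed by
    subject; ``manifest`` columns age, hdl, egfr on the same index.
    """
    merged = concentrations.join(manifest[["age", "hdl", "egfr"]], how="inner")
    if len(merged) < len(concentrations):
        lost = set(concentrations.index) - set(merged.index)
        raise ValueError(f"manifest missing covariates for subjects: {sorted(lost)[:5]}...")
    return merged.apply(
        lambda r: risk_score(r["APOA4"], r["CD5L"], r["IBP3"], r["age"], r["hdl"], r["egfr"], model),
        axis=1,
    )


def concordance_summary(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    allowable_diff: float = 5.0,
    pass_threshold_pct: float = 90.0,
) -> ConcordanceSummary:
    """Summarise agreement of paired risk scores.

    Reports the Pearson correlation, the per-subject absolute score
    differences (percentage points on the 0–100 scale), the fraction of
    subjects within ``allowable_diff`` points, and a verdict that passes
    only when that fraction strictly exceeds ``pass_threshold_pct`` of the
    cohort.  Degenerate (zero-variance) score lists yield an undefined
    correlation but still a verdict.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score lists differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired scores")
    if np.std(a) == 0 or np.std(b) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(a, b)[0])
    diffs = np.abs(a - b)
    frac = float(np.mean(diffs <= allowable_diff))
    return ConcordanceSummary(
        r=r,
        abs_differences=diffs,
        fraction_within=frac,
        allowable_diff=allowable_diff,
        pass_threshold_pct=pass_threshold_pct,
        passed=frac * 100.0 > pass_threshold_pct,
    )
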