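"""Bland-Altman difference plots and risk-score scatter figures."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .concordance import BlandAltmanResult


def bland_altman_plot(
    iams: Sequence[float],
    elisa: Sequence[float],
    ba: BlandAltmanResult,
    path: str | Path,
) -> None:
    """Difference (or log-ratio) vs pair mean, with bias and limits of agreement."""
    a = np.asarray(iams, dtype=float)
    b = np.asarray(elisa, dtype=float)
    if ba.mode == "additive":
        diff = a - b
        mean = (a + b) / 2.0
        center, lo, hi = ba.bias, ba.loa_lower, ba.loa_upper
        ylabel = "IAMS − ELISA (µg/mL)"
    else:
        diff = np.log(b) - np.log(a)
        mean = (np.log(a) + np.log(b)) / 2.0
        center, lo, hi = (np.log(ba.bias), np.log(ba.loa_lower), np.log(ba.loa_upper))
        ylabel = "log(ELISA / IAMS)"
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=12, alpha=0.7)
    for y, style in ((center, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="crimson", linestyle=style, linewidth=1)
    ax.set_xlabel("pair mean" + (" (µg/mL)" if ba.mode == "additive" else " (log µg/mL)"))
    ax.set_ylabel(ylabel)
    ax.set_title(f"{ba.analyte}: bias {ba.bias:.3g} ({ba.mode}), n={ba.n}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def score_scatter(
    scores_iams: Sequence[float],
    scores_elisa: Sequence[float],
    r: float,
    path: str | Path,
) -> None:
    """Paired risk scores from the two platforms with the identity line."""
    a = np.asarray(scores_iams, dtype=float)
    b = np.asarray(scores_elisa, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(a, b, s=12, alpha=0.7)
    lims = [min(a.min(), b.min()) - 2, max(a.max(), b.max()) + 2]
    ax.plot(lims, lims, color="grey", linewidth=1)
    ax.set_xlabel("risk score, IAMS")
    ax.set_ylabel("risk score, adjusted ELISA")
    ax.set_title(f"score concordance, R = {r:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
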