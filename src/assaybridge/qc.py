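"""Rolling mean ± 2SD batch acceptance from reference-plasma results.

Every MRM batch carries four replicates of a pooled reference plasma.
A batch is accepted when, for every analyte, the mean reference-plasma
concentration lies within two standard deviations of the rolling mean of
all previously accepted batches.  Until enough history has accumulated
for the SD to be stable (five batches by default), decisions are
*provisional*: the batch is accepted with a warning and still feeds the
rolling statistics.  Rejected batches are excluded from the rolling
statistics so an out-of-control run cannot drag the control limits along
with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class QCHistory:
    """Chronological per-batch mean reference-plasma concentrations."""

    analytes: list[str]
    records: list[dict] = field(default_factory=list)  # {"batch_id", <analyte>...}

    def append(self, batch_id: str, means: Mapping[str, float]) -> None:
        missing = set(self.analytes) - set(means)
        if missing:
            raise ValueError(f"batch {batch_id} missing analytes: {sorted(missing)}")
        self.records.append({"batch_id": batch_id, **{a: float(means[a]) for a in self.analytes}})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["batch_id", *self.analytes])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "QCHistory":
        df = pd.read_csv(path)
        analytes = [c for c in df.columns if c != "batch_id"]
        hist = cls(analytes=analytes)
        for row in df.itertuples(index=False):
            d = row._asdict()
            hist.append(str(d.pop("batch_id")), d)
        return hist

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class BatchDecision:
    batch_id: str
    decision: str  # accept | reject | provisional
    z_distances: dict[str, float]  # per-analyte |current - rolling mean| / SD
    reason: str


def gate_batch(
    history: QCHistory,
    batch_id: str,
    current: Mapping[str, Sequence[float]],
    n_sd: float = 2.0,
    min_history: int = 5,
) -> BatchDecision:
    """Gate one batch against the rolling statistics and update the history.

    ``current`` maps each analyte to its reference-plasma replicate
    concentrations (at least two).  With fewer than ``min_history`` prior
    batches the decision is provisional; otherwise the batch is rejected
    as soon as any analyte's mean falls outside mean ± ``n_sd``·SD of the
    rolling history.  Accepted and provisional batches are appended to the
    history; rejected ones are not.
    """
    if not current:
        raise ValueError("no reference-plasma results supplied for the batch")
    missing = set(history.analytes) - set(current)
    if missing:
        raise ValueError(f"current batch missing analytes: {sorted(missing)}")
    means: dict[str, float] = {}
    for analyte in history.analytes:
        vals = np.asarray(current[analyte], dtype=float)
        if len(vals) < 2:
            raise ValueError(f"{analyte}: need >= 2 reference replicates, got {len(vals)}")
        means[analyte] = float(vals.mean())

    frame = history.to_frame()
    z: dict[str, float] = {}
    outliers: list[str] = []
    if len(history) >= 2:
        for analyte in history.analytes:
            hist_vals = frame[analyte].to_numpy(dtype=float)
            mu = hist_vals.mean()
            sd = hist_vals.std(ddof=1)
            z[analyte] = abs(means[analyte] - mu) / sd if sd > 0 else (
                0.0 if means[analyte] == mu else float("inf")
            )
            if z[analyte] > n_sd:
                outliers.append(analyte)
    else:
        z = {a: float("nan") for a in history.analytes}

    if len(history) < min_history:
        decision = "provisional"
        reason = (
            f"only {len(history)} prior batch(es) (< {min_history}); "
            "accepted with warning, gate not yet armed"
        )
    elif outliers:
        decision = "reject"
        detail = ", ".join(f"{a}: |z|={z[a]:.2f}" for a in outliers)
        reason = f"reference plasma outside rolling mean ± {n_sd:g} SD for {detail}"
    else:
        decision = "accept"
        reason = f"all analytes within rolling mean ± {n_sd:g} SD"

    if decision != "reject":
        history.append(batch_id, means)
    return BatchDecision(batch_id=batch_id, decision=decision, z_distances=z, reason=reason)
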