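"""Gate MRM batches with the rolling mean ± 2SD reference-plasma rule.

Every batch carries four replicates of a pooled reference plasma; a
batch is accepted only when each analyte's mean lies within 2 SD of the
rolling mean over all previously accepted batches.
"""

from assaybridge import QCHistory, gate_batch, simulate_qc_batches

ref = {"APOA4": 110.0, "CD5L": 1.6, "IBP3": 0.36}
history = QCHistory(analytes=sorted(ref))
for i, batch in enumerate(simulate_qc_batches(ref, n_batches=20, seed=5)):
    history.append(f"day{i + 1}", {a: float(v.mean()) for a, v in batch.items()})
print(f"history: {len(history)} batches")

# an in-control batch
current = next(iter(simulate_qc_batches(ref, 1, seed=99)))
d = gate_batch(history, "batch21", current)
print(f"batch21: {d.decision} — " +
      ", ".join(f"{a} |z|={z:.2f}" for a, z in d.z_distances.items()))

# a batch whose CD5L drifted 30% high (e.g. a calibrator preparation error)
drifted = next(iter(simulate_qc_batches(ref, 1, seed=100)))
drifted["CD5L"] = drifted["CD5L"] * 1.3
d = gate_batch(history, "batch22", drifted)
print(f"batch22: {d.decision} — {d.reason}")
# The z-distances are |current mean − rolling mean| / rolling SD; any
# analyte beyond 2 rejects the whole batch, and rejected batches never
# enter the rolling statistics.
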