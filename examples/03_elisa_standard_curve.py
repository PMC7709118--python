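"""Fit a 7-point 4PL ELISA standard curve and quantify sample wells.

Simulates one CD5L plate (7 standards, low/high QCs, blank, sample wells
at the 1-in-1600 plasma dilution), fits OD = d + (a-d)/(1+(x/c)^b), and
inverts the curve to plasma concentrations.
"""

from assaybridge import CohortSpec, default_analytes, generate_cohort
from assaybridge.elisa import quantify_plate
from assaybridge.synthetic import default_curve, elisa_measured_concentrations, simulate_elisa_plate

cfg = default_analytes()["CD5L"]
spec = CohortSpec(n_subjects=10, rng_seed=3)
truth = generate_cohort(spec)
measured = elisa_measured_concentrations(truth, spec, seed=3)

plate = simulate_elisa_plate(
    measured["CD5L"], "CD5L", default_curve(cfg), cfg.dilution_factor, seed=3
)
table, curve, qc_passed = quantify_plate(plate, "CD5L")

print(f"4PL fit: a={curve.a:.3f}, b={curve.b:.3f}, c={curve.c:.2f} ng/mL, "
      f"d={curve.d:.3f}, R² = {curve.r_squared:.4f}")
print(f"plate QC (low/high recoveries within ±20% of nominal): "
      f"{'pass' if qc_passed else 'FAIL'}")
print()
print(table.head(6).to_string(index=False))
# Plasma concentration = assay concentration (ng/mL) x dilution factor /
# 1000; an R² >= 0.99 on the standards is the usual release criterion for
# a plate, alongside the QC recoveries.
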