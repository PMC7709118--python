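"""Quantify an immunoaffinity-MRM batch from a transition-level report.

Simulates one 96-well batch (4 calibrators, 4 reference-plasma wells,
blanks, and samples), then runs the full quantitation chain: S/N > 5
filtering, light/heavy ratioing, single-point calibration, and flagging
against the plasma working ranges.
"""

from assaybridge import CohortSpec, IamsBatchLayout, RunConfig, generate_cohort
from assaybridge.mrm import quantify_batch
from assaybridge.synthetic import simulate_iams_batch

config = RunConfig()
spec = CohortSpec(n_subjects=20, rng_seed=7)
truth = generate_cohort(spec)
report = simulate_iams_batch(truth, IamsBatchLayout(), spec, seed=7,
                             analytes=config.analytes)
print(f"transition report: {len(report)} rows "
      f"({report.sample_id.nunique()} wells x 3 peptides x light/heavy)")

table, factors = quantify_batch(report, config)
for name, rf in factors.items():
    print(f"{name}: calibrator effective conc {rf.calibrator_effective_conc:.3g} µg/mL, "
          f"mean ratio {rf.mean_calibrator_ratio:.3f}, replicate CV {rf.replicate_cv:.1%}")

samples = table[table.well_role == "sample"]
print()
print(samples.head(6).to_string(index=False))
# Each sample concentration is (calibrator effective concentration) x
# (sample light/heavy ratio) / (mean calibrator ratio); flags mark results
# outside the assay's plasma working range or failing the S/N filter.
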