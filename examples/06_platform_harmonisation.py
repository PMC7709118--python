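"""Harmonise ELISA to the MS platform and compare composite risk scores.

A paired 100-subject cohort is measured on both platforms with the
built-in inter-platform biases (ELISA low by ~48 µg/mL for APOA4 and
~0.5 µg/mL for CD5L; high by a factor ~9.5 for IBP3).  Bland-Altman
analysis estimates each bias, the ELISA values are adjusted, and the
0–100 risk scores from the two platforms are compared.
"""

import pandas as pd

from assaybridge import (
    CohortSpec,
    RiskModelConfig,
    apply_adjustment,
    bland_altman,
    concordance_summary,
    elisa_measured_concentrations,
    generate_cohort,
    iams_measured_concentrations,
    risk_scores_table,
)

spec = CohortSpec(n_subjects=100, rng_seed=8)
truth = generate_cohort(spec)
iams = iams_measured_concentrations(truth, spec, seed=18)
elisa = elisa_measured_concentrations(truth, spec, seed=28)

adjusted = {}
for name, sim in spec.analytes.items():
    ba = bland_altman(iams[name], elisa[name], mode=sim.bias_mode, analyte=name)
    adjusted[name] = apply_adjustment(elisa[name].to_numpy(), ba)
    what = (f"+{ba.bias:.2f} µg/mL added to ELISA" if ba.mode == "additive"
            else f"ELISA divided by {ba.bias:.2f}")
    print(f"{name}: {ba.mode} bias — {what} "
          f"(LoA [{ba.loa_lower:.3g}, {ba.loa_upper:.3g}], t={ba.t_statistic:.1f}, "
          f"p={ba.p_value:.2g}, n={ba.n})")

model = RiskModelConfig()
manifest = truth[["age", "hdl", "egfr"]]
scores_ms = risk_scores_table(iams, manifest, model)
scores_elisa = risk_scores_table(pd.DataFrame(adjusted, index=truth.index), manifest, model)

summary = concordance_summary(scores_ms.to_numpy(), scores_elisa.to_numpy())
print()
print(f"risk-score correlation R = {summary.r:.3f}")
print(f"{summary.fraction_within:.0%} of subjects within "
      f"{summary.allowable_diff:g} score points — "
      f"{'PASS' if summary.passed else 'FAIL'} (threshold > 90%)")
# A significant t-test before adjustment simply confirms the platforms
# disagree systematically; what matters clinically is that, after the
# Bland-Altman adjustment, more than 90% of subjects get risk scores
# within 5 points of each other on either platform.
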