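# Methods

This note documents the models implemented in `assaybridge`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want written
down.

## MRM quantitation (stable-isotope dilution)

Each well receives a fixed spike (400 fmol) of a ¹³C/¹⁵N-labelled peptide
per target protein. Transition areas are summed per (peptide, label)
before any ratio is formed — with several transitions per peptide this is
the standard robust choice, since weak transitions then contribute signal
without dominating the noise. The signal-to-noise of a summed peak is
`Total Area / Total Background`; a peptide measurement is usable only when
both the light and the heavy peak exceed S/N 5 (strict inequality). Zero
background with positive area counts as detected (infinite S/N); a
(0, 0) peak means nothing was integrated and the measurement is reported
missing rather than failed.

Quantitation is single-point: the calibrator wells' light/heavy ratios are
averaged (after S/N filtering; at least two survivors required, replicate
CV must be < 20% or the batch aborts) and an unknown's concentration is

    C = C_cal_effective · r_sample / r̄_cal.

The calibrator's *effective* concentration accounts for the volume
difference between calibrator wells (50 µL of solution) and plasma wells
(10 µL): `C_eff = c_solution × V_cal / V_plasma`. For the three analytes'
documented solution concentrations (18.3, 0.686, 0.178 µg/mL) this gives
91.5, 3.43 and 0.890 µg/mL. Published figures for the latter two are 3.45
and 0.892; the formula value is used, since the provenance of the extra
0.02 is unknown (most plausibly rounding at an intermediate step). The
difference is ≤ 0.6% and immaterial downstream, but it is deliberately not
forced to match.

This chain presumes the response ratio is linear through the origin in
concentration — the premise of single-point calibration — which holds by
construction in the simulator and is verified empirically by the linearity
module on dilution series.

Out-of-range results are reported with `below_lod` / `above_range` flags
rather than censored: the method-agreement analysis downstream needs its
pairs intact, and the flags carry the uncertainty.

## ELISA quantitation

Standard curves use the four-parameter logistic

    OD(x) = d + (a − d) / (1 + (x/c)^b)

with `a` the zero-concentration asymptote, `d` the saturating asymptote,
`c` the inflection (ng/mL) and `b` the slope. The fit is unweighted least
squares on OD (`scipy.optimize.curve_fit`), initialised at the observed OD
extremes, geometric-mean concentration, unit slope — sufficient on
well-behaved sigmoid data; non-convergence is surfaced as an error naming
the analyte. At least five distinct levels are required. The inverse is
closed-form:

    x = c · ((a − d)/(OD − d) − 1)^(1/b),

defined only strictly between the asymptotes; outside, the well is flagged
(toward `a` ⇒ below detection, toward `d` ⇒ above range) with no value.
Blank OD is not subtracted by default — the lower asymptote absorbs it.

Plasma concentration is `assay ng/mL × dilution / 1000` µg/mL, with
dilutions 400 / 1600 / 200 per analyte. Note the assay ranges and
dilutions imply plasma ranges of 2.656–170, 0.256–16.0 and 0.126–8.0
µg/mL; published lower bounds are rounded (2.60, 0.26, 0.13) and the
computed values are used as-is.

Plate release requires every low/high QC well to back-calculate within
±20% of nominal — the ligand-binding accuracy criterion, adopted because
the ELISA's own QC limits are not documented.

## Validation criteria

* **Linearity**: OLS of measured on nominal over ≥ 5 levels × ≥ 2
  replicates; R², slope, per-level recovery and CV.
* **LOD**: lowest level at which *every* replicate is individually
  distinguishable from blank — the platform's S/N > 5 flag, or signal
  above mean(blank) + 3·SD when blank readings exist. The rule is recorded
  in the output because no formula is documented for the published LODs,
  which therefore cannot be reproduced exactly.
* **LOQ**: lowest detected level with mean recovery within 20% of nominal
  and replicate CV < 20%.
* **Precision**: intra-assay CV is the *mean of within-batch CVs*
  ("average % CV"); inter-assay CV is the CV of batch means. All CVs are
  sample CVs (ddof = 1) in percent.
* **Stability**: per condition and *per plasma sample*, %difference of the
  stressed arm mean against the paired baseline arm, passing at
  |%diff| ≤ 20 with both arms' CVs < 20. Per-sample evaluation matters:
  pooling donors mixes ~15% biological spread into the CV criterion and
  fails stable analytes spuriously. A freeze-thaw summary (mean CV across
  0–3× cycles per sample, averaged over samples) is also provided.

## Batch QC gate

A batch is accepted when, for every analyte, the mean of the four
reference-plasma replicates lies within 2 sample-SDs of the rolling mean
over all prior accepted batches. Decisions with fewer than five prior
batches are *provisional* (accepted with a warning) because an SD from
fewer points is too unstable to gate on. Rejected batches are excluded
from the rolling statistics so an out-of-control run cannot widen its own
limits. One caution discovered during development and worth keeping in
mind: *building* a history by gating each batch against the forming
statistics is unstable — an early tight cluster rejects subsequent
in-control batches and the rolling SD ratchets downward. A pre-existing
ledger should be seeded from all acquired batches.

With three analytes gated independently at ±2SD, the in-control
false-rejection rate is ≈ 1 − 0.9545³ ≈ 13% when the current batch is
drawn from the same distribution as the history (verified by simulation in
the tests). In routine operation the rate is much lower because a single
batch's mean deviates by its within-day error (~3.5%) while the rolling SD
reflects full inter-assay variation (~9%).

## Cross-platform harmonisation

Bland-Altman analysis runs per analyte in one of two configured modes —
never auto-switched, though a diagnostic (correlation of difference with
pair mean) is reported to support the choice:

* **additive** (APOA4, CD5L): differences `d = IAMS − ELISA`; bias =
  mean(d) is the amount *added* to the ELISA values; limits of agreement
  bias ± 1.96·SD(d).
* **multiplicative** (IBP3): log-scale differences; the reported bias is
  the geometric mean ratio ELISA/IAMS, i.e. the *divisor* applied to the
  ELISA values; limits of agreement back-transform to factors.

These sign conventions make the reported number literally the correction
applied to the ELISA, matching how such adjustments are quoted. A
one-sample two-sided t-test (`t = mean/(SD/√n)`, df = n−1, α = 0.05)
assesses zero bias on the working scale; with SD = 0 the test degenerates
to t = 0, p = 1 for identical pairs and |t| = ∞, p = 0 for a nonzero
constant offset. After adjustment the mean (log-mean) paired difference is
zero to numerical precision, which the tests assert at 10⁻¹⁰. The
adjustment is estimated in-sample on the same cohort it is applied to.

The composite risk score is `100 × logistic(β₀ + Σ βᵢxᵢ)` over the three
(adjusted) biomarker concentrations plus age, HDL-cholesterol and eGFR.
The true coefficients are proprietary and unpublished; the packaged
defaults are a **synthetic placeholder** with plausible signs (risk rises
with CD5L, IBP3, age; falls with APOA4, HDL, eGFR) and magnitudes chosen
so that cohort scores spread over roughly 10–90. Any conclusion about
absolute scores therefore applies to the placeholder model only;
concordance *between platforms* is largely insensitive to the coefficient
values, which is the quantity this package actually tests. Coefficients
are config-overridable.

Concordance is summarised by the Pearson correlation of paired scores and
the fraction of subjects within an allowable difference, interpreted as
**5 absolute points on the 0–100 scale** (relative differences are
unstable near zero risk); the cohort passes when the fraction strictly
exceeds 90%. Both thresholds are configurable.

## Synthetic-data generator

The generator defines the study conditions for every test:

* **Cohort**: 100 subjects. True concentrations are log-normal — strictly
  positive and right-skewed like plasma proteins — with geometric CV
  defined as `exp(SD(log x)) − 1`. Medians: APOA4 110 µg/mL, CD5L 1.6,
  IBP3 0.36. CD5L and IBP3 sit at the geometric midpoint of the overlap
  of the two platforms' plasma working ranges; APOA4 sits higher than its
  midpoint so that the −47.93 µg/mL ELISA offset cannot push low-tail
  readings near zero, consistent with typical plasma APOA4 around
  100–150 µg/mL. Covariates: age N(65, 9) clipped to 30–90 y, HDL
  log-normal median 1.2 mmol/L (GCV 25%), eGFR N(75, 18) clipped to
  15–120 mL/min/1.73 m² — a plausible type-2-diabetes cohort.
* **Platform noise**: 5% multiplicative per measurement on each platform.
* **Inter-platform bias** (applied to the ELISA reading): −47.93 µg/mL
  (APOA4), −0.53 µg/mL (CD5L), ×9.52 (IBP3) — the magnitudes and modes of
  the published difference plots, so bias-recovery tests target known
  truth.
* **MRM batch**: one 96-well plate holds 4 calibrator wells, 4 reference
  wells, 2 blanks, a double blank and up to 85 samples; larger cohorts
  split into consecutive batches with their own calibrators. The response
  ratio is `slope × plasma-equivalent concentration` (slope defaults to
  1/C_eff so calibrator ratios sit near 1) with log-normal ratio noise;
  heavy areas fluctuate around 10⁶ counts but cancel in the ratio, as in
  real isotope dilution. Blanks carry light signal at background level
  (S/N ≈ 1, failing the filter); the double blank, processed without
  antibody beads, has neither light nor heavy signal above background.
* **ELISA plate**: 7 standards on a geometric ladder across the assay
  range, low/high QCs at the 25th/75th geometric quantiles, a blank, one
  well per subject; OD = 4PL + N(0, 0.01) absorbance noise on a ~1.55 AU
  span.
* **QC history**: reference-plasma batches carry 5% replicate noise plus a
  9% batch-level shift bundling calibration error and day-to-day response
  drift, so the simulated inter-assay CV of batch means lands near the
  ≈9–11% typical of such assays in long-run operation (and the simulated
  precision report correspondingly shows intra ≈ 5%, inter ≈ 9%).
* **Seeding**: one integer seed; sub-generators draw from independent
  `numpy` seed-sequence streams, so outputs are byte-reproducible and
  arms are statistically independent.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: chromatographic peak shapes and integration
error (areas are simulated directly), interference and cross-reactivity,
plate spatial (edge-well) effects, carry-over, hemolysis/lipemia matrix
effects, non-linear MRM response at range extremes, and real biological
covariance between the three analytes (they are drawn independently).
Concentration-dependent (proportional) measurement error is modelled, but
a mixed additive+proportional error structure is not.

## Problem sizes

Defaults keep every check cheap while preserving the study geometry: the
paired cohort is n = 100 (two MRM batches); bias recovery uses 20 seeded
replicate cohorts; the QC in-control rate uses 600 simulated batch
decisions against 60-batch histories; precision uses 20 batches of 4
replicates. The full test suite and the acceptance script each run in
well under a minute on one core.

## Known limitations

* The LOD/LOQ rules are this package's documented choices; published LODs
  were derived from raw data not available here and are not reproducible.
* The risk-model coefficients are placeholders (above).
* The Bland-Altman adjustment is a constant (or constant-factor) shift; no
  regression-based (Deming, Passing-Bablok) harmonisation is provided.
* The multi-analyte 2SD gate has a non-trivial family-wise false-rejection
  rate by construction; no multi-rule scheme is layered on top.
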