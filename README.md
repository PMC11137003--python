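# patrace

Stable-isotope tracer metabolomics for propionate metabolism: a tested,
reusable pipeline for the analyses behind fed-vs-fasted studies of
propionic acidemia (PA) mouse models.

PA blocks propionyl-CoA carboxylase, so propionyl-CoA accumulates and
its biomarkers (propionylcarnitine "C3", the C3/C2 ratio, methylcitrate)
rise. Quantifying what fasting does to these pools requires four
computations that this package implements end to end:

- **MID natural-abundance correction** — measured mass-isotopologue
  distributions of derivatized fragments are deconvolved to tracer-only
  mol fractions by non-negative least squares against a correction
  matrix built from elemental formulas, derivatization deltas and tracer
  purity; summarized as average carbon labeling Σ(mᵢ·i)/n.
- **Glucose production** — a [6,6-²H₂]glucose bolus decays as
  E(t) = E0·e^(−kt); with dose D, Q = D(1−E0)/E0 and Ra = k·Q give the
  glucose pool and its rate of appearance (µmol·kg⁻¹·min⁻¹).
- **Internal-standard quantification** — concentrations from analyte/IS
  peak-area ratios, plasma ammonia from a ¹⁵N spike, and PCC/SDS/BCAT
  enzyme activities (nmol·min⁻¹·mg⁻¹); plus a registry self-check that
  recomputes every MRM precursor m/z from formula arithmetic.
- **Biomarker statistics** — C3/C2 and methylcitrate/citrate ratios,
  fold changes, one-tailed pooled t tests, one-way ANOVA with a
  Monte-Carlo Dunnett post-hoc, and volcano tables.

A synthetic-cohort generator (`patrace.synth`) emulates the two-group
design (N = 5 per group), tracer label cascades, forward
natural-abundance convolution and bolus time courses with known ground
truth, so every stage is verifiable without measured data.

## Worked example

```python
import numpy as np
from patrace import chem, mid, turnover

# 1. the printed MRM precursor of propionate's 3-NPH derivative
f = chem.apply_derivative(chem.parse_formula("C3H6O2"), "3NPH")
print(chem.ion_mz(f, "[M-H]-"))                # 208.0

# 2. correct a measured propionylcarnitine MID and summarize labeling
ctx = mid.fragment_context("propionylcarnitine")       # methylated, 13C3
M = mid.build_correction_matrix(ctx)
true = np.array([0.7, 0.2, 0.05, 0.05])                # M0..M3
meas = mid.forward_convolve(mid.MIDVector(true, "corrected", 3), M)
corrected, resid = mid.correct_mid(meas, M)
print(np.round(corrected.fractions, 6))        # [0.7 0.2 0.05 0.05]
print(mid.average_carbon_labeling(corrected))  # 0.15

# 3. glucose production from a bolus decay course
t = np.array(turnover.STANDARD_TIME_POINTS)
tc = turnover.EnrichmentTimeCourse(t, 0.109 * np.exp(-0.083 * t))
fit = turnover.fit_decay(tc)
est = turnover.estimate_ra(fit, turnover.BolusDose())
print(round(est.ra_umol_per_kg_min, 1))        # 149.1
```

The corrected MID returns exactly the tracer-only fractions that
generated the measurement (residual ≈ 0), the labeling summary says 15%
of the three labelable carbons carry tracer, and the bolus fit recovers
a glucose production of ≈149 µmol·kg⁻¹·min⁻¹ from the decay curve.

The same stages run from the shell:

```sh
patrace simulate --out run --seed 7
patrace correct   --input run/mids.csv       --out run/corrected.csv
patrace quantify  --input run/peak_areas.csv --out run/concentrations.csv
patrace turnover  --input run/bolus.csv      --out run/turnover.csv
patrace biomarkers --input run/concentrations.csv --out run/biomarkers
patrace report    --run run
patrace mrm-check
```

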