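# attamech

Developmental biomechanics of the leaf-cutter ant bite apparatus.

In many social insects, freshly eclosed workers (*callows*) stay in the nest
and only older workers forage — age polyethism.  For leaf-cutter ants
(*Atta vollenweideri*), foraging means cutting tough leaf lamina with bite
forces around 100 mN, and a biomechanical explanation of the behavioural
transition is testable: does the musculoskeletal bite apparatus simply not
*work* yet in young workers?  `attamech` implements the full inference chain
used to answer that question, for researchers in comparative biomechanics
and social-insect biology:

- **brightness** — cuticle brightness `b_RGB = (R+G+B)/(3·255)` from
  photograph ROIs as an age-since-eclosion proxy, with a known-age
  calibration (0.37 ± 0.04 at 1 day → 0.24 ± 0.04 at 5 days).
- **thickness** — per-voxel local thickness of a segmented head-capsule
  cuticle mask by the maximal-inscribed-sphere (Hildebrand–Rüegsegger)
  definition, validated on shell phantoms.
- **indentation** — indentation modulus `E_I` from trapezoidal
  load–displacement traces by Oliver–Pharr analysis of the unloading curve:
  `S = dP/dh`, `h_c = h_max − ε P_max/S`, `E_r = (√π/2)·S/√A(h_c)`.
- **rigidity** — thin-plate flexural rigidity
  `D = E_I·T_hc³ / (12(1−ν²))` (mN·mm), the deformation proxy
  `κ = F_b/D` (mm⁻¹) and strain proxy `κ̂ = κ/T_hc` (mm⁻²), plus
  intercept-free ratio statements over a brightness interval:
  `D(b₁)/D(b₂) = (b₁/b₂)^(s_E + 3 s_T)` for log–log slopes `s_E`, `s_T`.
- **stats** — allometric log₁₀–log₁₀ OLS with t-based CIs (bite force vs
  muscle volume against the theoretical exponent interval [2/3, 1]) and the
  Spearman rank-correlation suite against brightness.
- **foraging** — cuttable fraction of a leaf cutting-force population
  (median 82 mN, range 7–828 mN), fragment-carriage weight and the closer
  muscle force budget.
- **synthetic** — a calibrated generator for cohorts, voxel phantoms,
  indentation traces and leaf populations, so the entire chain runs and is
  testable without animals, scans or an indenter.

## A worked example

```python
from attamech import (CohortParams, generate_cohort, fit_imputation,
                      rigidity_profile, flexural_rigidity)

cohort = generate_cohort(CohortParams(seed=2))      # 49 ants, 14 foragers
model = fit_imputation(cohort)                      # E_I(b), T_hc(b) on log-log axes
profile = rigidity_profile(model, 0.13, 0.52, extrapolate=True)
print(round(model.modulus_fit.slope, 2), round(model.thickness_fit.slope, 2))
print(round(profile.D_ratio, 1), round(profile.modulus_factor, 1))
print(round(flexural_rigidity(7.2, 31.0), 1))
```

prints

```
-0.57 -0.63
30.5 2.2
19.6
```

the fitted brightness slopes of modulus and thickness for this simulated
cohort, the resulting rigidity ratio between the darkest (b = 0.13) and
brightest (b = 0.52) cuticle with the modulus component separated out
(rigidity changes ~30-fold here, only a factor ~2 of which is material
stiffening — the rest is cuticle thickening, which enters cubed), and the
absolute rigidity at the forager group means (7.2 GPa, 31 μm → 19.6 mN·mm).
The `examples/` directory has one short narrative script per capability;
each builds its own input and explains what it prints.

A thin CLI mirrors the library (`attamech simulate|thickness|indent|
rigidity|stats|forage|pipeline`); `attamech pipeline` runs the whole
simulate → measure → impute → rigidity → stats → foraging chain and writes
CSV/JSON artifacts plus a seeded, reproducible report.

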