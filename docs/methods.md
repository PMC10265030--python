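# Methods

This note documents the models, conventions and numerical choices behind
`attamech`, and what the synthetic-data generator does and does not emulate.

## Study system and observables

Small *Atta vollenweideri* workers (3–7 mg) are sampled from callow to
forager stage.  Worker age after eclosion is not observable in a colony
sample, so cuticle brightness `b_RGB = (R+G+B)/(3·255)` serves as the
ageing proxy: cuticle darkens as it sclerotizes.  All analyses are therefore
regressions and rank correlations *against brightness*, not age; age enters
only through a small known-age calibration set (brightness 0.37 ± 0.04 one
day post eclosion, 0.24 ± 0.04 at five days).

## Brightness (module `brightness`)

ROI channel means are averaged over a rectangle or a circle
(centre-distance ≤ radius inclusion).  An optional per-image linear gain per
channel maps printed colour-stripe ROIs onto reference RGB values; the
stripe is a baseline, so the correction is off by default and applied only
on request.  The brightness → age map interpolates age piecewise-linearly in
log-brightness through the known-age group means; outside the calibrated
brightness range it returns the boundary age with a censored flag
(`younger_than_min_age` / `older_than_max_age`), because sclerotization
saturates and the calibration only supports bounds.  The calibration F
statistic treats age as a single continuous regressor (df = 1, n − 2).

Known confound, deliberately left uncorrected and visible in reports:
brightness co-varies weakly with body mass in real cohorts; no correction is
specified by the measurement model, so none is applied.

## Voxel local thickness (module `thickness`)

Local thickness at a voxel is the diameter of the largest sphere that fits
inside the structure and contains the voxel.  Implementation: exact
Euclidean distance transform (scipy) → inscribed radius per foreground
voxel → sphere propagation (each voxel keeps the largest covering
diameter).

**Discretization convention.**  Radii are quantized to whole voxels:
r = ⌊EDT⌋, and a sphere is admissible when no background voxel centre lies
*strictly* inside it (touching is allowed).  The reason is a subtle bias:
raw centre-to-centre radii (thickness 2·EDT) acquire a sub-voxel excess
wherever the discrete boundary happens to fall favourably between lattice
shells, and the max in the propagation step collects these lucky spheres,
inflating a 10 px cylindrical shell by ≈3%.  Radius quantization removes the
excess while keeping the distance geometry exact.  Consequences, measured on
phantoms: even-width slabs and integer-radius balls are recovered exactly;
odd-width slabs read one voxel high (no lattice centre sits on their
mid-plane — the same parity behaviour documented for the reference
sphere-fitting implementations); a 10 px hollow-cylinder shell is recovered
to −0.33% and a 10 px spherical shell to −0.07%.  The provable lower bound
under this convention is thickness ≥ 2·(EDT − 1).  Masks must be padded with
background where the structure touches the array border (the border itself
is not background).  Summaries use the population SD (whole-map summary, not
a sample estimate), and CV = SD/mean.

Masks are taken as given (segmentation is out of scope); an optional
one-voxel erosion emulates a conservative segmentation stance.  Cross-section
photograph measurements (`section_thickness`) are plain Euclidean lengths of
user-digitized boundary pairs.

## Nanoindentation (module `indentation`)

Traces are segmented by displacement rate (ramps above 25% of the peak rate;
the plateau between them is the hold).  The unloading branch is fitted with
`P = α(h − h_f)^m` by linear least squares in log space with a bounded
scalar search over `h_f`; the default fit window keeps samples between 20%
and 95% of the peak unloading load, avoiding final-contact-loss artefacts.
Contact stiffness is evaluated analytically at peak displacement.  Then

    h_c = h_max − ε P_max / S   (ε = 0.75, Berkovich)
    E_r = (√π/2) · S / √A(h_c)
    1/E_r = (1 − ν_s²)/E_s + (1 − ν_i²)/E_i

with a diamond indenter by default (E = 1141 GPa, ν = 0.07), sample Poisson
ratio 0.3, and the ideal Berkovich area function A = 24.5·h_c² unless a
calibrated polynomial is supplied.  The reported indentation modulus is the
Young's form by default (`plane_strain` optional); the Poisson ratio is
carried in the result because the conversion depends on it.  Hardness
H = P_max/A(h_c) is computed but not analysed further.  No creep or thermal
drift correction is applied by default — the 20 s hold mitigates creep.
Where one sample yields many indents, the arithmetic mean over accepted
indents is the per-sample summary (flagged; region weighting is not
specified by the measurement model).

Round-trip accuracy on synthetic traces: ≤ 2% noise-free across
0.5–30 GPa (the span of published insect-cuticle moduli), ≤ 10% at twice
the sensor noise scale (1 μN).

## Rigidity, deformation and strain proxies (module `rigidity`)

The head capsule is treated as a thin plate in bending:
`D = E_I T_hc³ / (12(1−ν²))` with ν = 0.3, in mN·mm from GPa and μm
(1 GPa·μm³ = 10⁻³ mN·mm; all conversions live in `units.py`).  κ = F_b/D
and κ̂ = κ/T_hc are *proxies* — proportional to deflection and strain up to
a missing squared length scale set by head dimensions — so they are reported
with explicit units (mm⁻¹, mm⁻²) and never converted to strain percent.

Modulus and thickness samples are small and unpaired, so both are regressed
on brightness (log₁₀–log₁₀ OLS on the measured subsets only) and predicted
for every ant from its measured brightness; filled values carry an
`imputed` provenance flag.  Ratio statements over a brightness interval
cancel the intercepts: `D(b₁)/D(b₂) = (b₁/b₂)^(s_E+3s_T)`; the profile and
the equal-load deflection ratio share this closed form and agree to machine
precision.  Absolute D values require intercepts, which are anchored at the
forager group means (7.2 GPa, 31.0 μm at brightness 0.17) and are therefore
labelled anchor-dependent; ratios are anchor-free.  The default reporting
interval is the observed brightness range 0.13–0.52, and the deflection
example uses the 0.15/0.50 pair.

## Scaling statistics (module `stats`)

Power laws are fitted by OLS on log₁₀-transformed data (closed-form, t-based
95% CIs via statsmodels; validated against the textbook formula in tests).
The muscle-scaling exponent is compared with the closed interval [2/3, 1]
(geometric similarity to constant fibre length); the verdict uses the point
estimate, with CI overlap reported alongside.  Spearman's ρ uses average
ranks for ties and a t-approximation p-value with df = n − 2; the type-I
error at the study's n = 49 calibrates to ≈5% in simulation.  p-values are
reported uncorrected for multiple testing, mirroring conventional reporting
of such correlation tables; both t and rank-sum two-sample tests are always
available because normality of brightness cannot be assumed.

## Foraging ability (module `foraging`)

The cuttable fraction is the empirical CDF of a leaf cutting-force
population at the ant's maximum bite force, ties counted as cuttable (the
cutting force is a threshold the bite must reach).  Whether "half the
leaves" means the median comparison or the CDF value is a convention; the
CDF is used and the median comparison reported alongside.  Carriage force is
fragment mass × g (15 mg → 0.147 mN) and the muscle force budget is fibre
count × per-fibre force (1000 × 0.70 mN = 700 mN), expressed also as a
multiple of body weight.

## Synthetic-data generator (module `synthetic`)

The generator encodes the study conditions; all downstream code treats its
output like measured data.

* **Cohort structure**: 49 ants, 14 foragers (brightness ~ N(0.17, 0.03),
  clipped to range) and 35 callows (brightness ~ U(0.13, 0.52); the within-
  callow brightness distribution is not constrained by the sampling design,
  which selected visibly bright ants, so uniform over the observed range is
  assumed).  Age is generator-internal metadata from an exponential decay
  through the two day anchors; no analysis uses it.
* **Power laws**: modulus and thickness follow brightness power laws with
  slopes −0.50 and −0.62, anchored at the forager means; muscle and cuticle
  volume power laws pass through the printed bright-callow/forager group
  anchors (0.08→0.51 and 0.09→0.22 mm³).  Bite force is generated from
  muscle volume as F_b = c·V_m^1.64, with c anchored so F_b(0.51 mm³) =
  102 mN.
* **Noise**: multiplicative lognormal with mean 1 on every positive
  quantity — positivity is guaranteed and the log₁₀ OLS model of the
  analysis is exact.  Residual variances are tuned so the expected R²
  matches the calibration targets (0.85 force, 0.43 modulus, 0.87
  thickness) given the realized regressor spread; muscle volume carries a
  fixed log₁₀ SD of 0.17 (CV ≈ 0.4).
* **Anchor semantics**: anchors fix the *median* of each power law at the
  reference brightness; arithmetic group means sit above the anchors by the
  lognormal convexity factor (≈1.08 for volumes, ≈1.2–1.3 for force given
  the within-group brightness spread).  The printed group means for force
  (102 vs 8 mN) and muscle volume (0.51 vs 0.08 mm³) are mutually
  inconsistent with a single exponent of 1.64 (0.51/0.08 = 6.4 and
  6.4^1.64 ≈ 21 ≠ 102/8); the generator gives priority to the allometric
  exponent, so simulated bright-callow mean force is ≈5 mN — the same order
  as, and within one printed SD of, the 8 ± 6 mN group value.
* **Phantoms** are rasterized by voxel-centre inclusion with half-open
  annuli (inner < r ≤ outer), so a shell of nominal thickness t spans
  exactly t voxel layers along a radial lattice line; metadata records the
  truth.  Rasterization is deterministic.
* **Indentation traces** follow the 5/20/5 s trapezoid with 300 nm peak
  displacement; the unloading branch is the Sneddon power law whose
  analytic stiffness matches the requested modulus and the active area
  function (residual depth 0.4·h_max, exponent m = 1.5), the hold is flat
  (optional linear creep), and Gaussian load noise is added on request.
* **Leaf population**: lognormal with log-median = log(82 mN).  The printed
  bounds (7, 828) are slightly asymmetric about the median on the log scale,
  so σ is set from the tighter bound at the 99.5th percentile
  (σ = ln(828/82)/z₀.₉₉₅ ≈ 0.90); ≈0.8% of the mass falls outside the
  bounds.  A degenerate range returns a point mass.

What the generator does **not** emulate: colony effects (colony is a label
only), the brightness–body-mass confound, measurement error in brightness
itself, muscle-fibre ultrastructure and detachment, within-head spatial
structure of thickness (per-ant thickness SD is generated from a smooth CV
trend, not from a 3D model), and real partial-volume segmentation artefacts.
Passing tests therefore demonstrate that the analysis chain is correct and
well-calibrated under the stated statistical structure — not that it is
robust to every artefact of real tomographic or photographic data.

## Reproducibility and problem sizes

All randomness flows from one root seed through named substreams
(`pipeline.substream_seed`), so identical seeds give byte-identical outputs
and any stage can be re-run from saved intermediates.  Default problem
sizes: the phantom validation uses the 40/30 × 100 px cylinder
(≈2.2 × 10⁵ shell voxels, seconds on one core); parameter-recovery suites
use 200–500 cohorts of the study's sizes (n = 10–12); the leaf population
uses 10⁵ draws; brute-force oracle comparisons run on ≤ 16³ lattices where
exhaustive search is feasible.

## Known limitations

* The thickness estimator's odd-width +1 px parity bias is inherent to
  lattice-centred spheres; sub-voxel structures (1 px) read as 2 px.
* Tomographic thickness means of real heads are pulled upward by locally
  thickened regions (e.g. around the mandible articulations); no region
  masking is applied because no exclusion rule is part of the measurement
  model.
* Absolute plate deflections are out of scope (they require the missing
  length scale and an external load constant); only ratios are exposed.
* The brightness → age map is a two-to-three-point interpolation and should
  be treated as bounds ("younger than 1 day", "older than 5 days") outside
  its anchors.
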