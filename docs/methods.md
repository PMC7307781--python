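# Methods

## Dose model

Each treatment field is modelled as a separable product of a lateral profile
and a depth-dose curve, `D(x, y, z) = L(x) · P(z)`, constant along y (the
direction parallel to the beam planes). This mirrors how planar-array SFRT
dosimetry is measured in practice — a surface film for the lateral structure
and a sagittal film for depth — and makes every volumetric quantity
computable as a weighted 2-D integral.

**Lateral profile.** Trapezoidal: rectangular plateaus at the measured
surface peak and valley doses joined by linear penumbra ramps of width
`penumbra_width` placed outside the aperture edge (so the aperture width is
the plateau width and the width at 50 % level is `aperture + penumbra`).
Defaults: 0.05 mm for the 0.31 mm minibeam collimator, 0.5 mm for the
broad-field/half-field/2 mm collimators. Measured profiles show up to ~10 %
peak-dose non-uniformity across the field; the model keeps plateaus flat
because no tabulated non-uniformity exists to fit. Arrays fall to the
valley (scatter floor) outside the 20 mm field; uniform and half fields
fall to zero.

**Depth dose.** A single effective exponential `P(z) = e^(−μz)`, the
simplest monotone curve consistent with the two printed numbers available
for the open field: 20.8 Gy at the surface and 20 Gy averaged over the 1 cm
tumour depth. Solving `(1 − e^(−10μ))/(10μ) = 20/20.8` by bisection gives
μ = 0.0079 /mm, applied to all arms (all used the same 320 kV beam).
Real kV depth dose has buildup and scatter structure this ignores; the
error is shared across arms, which is what an inter-arm comparison needs.

**Grid.** Half-open voxel bins; lateral axes sampled at bin centres, depth
at each bin's upper surface so z = 0 (where the peak surface dose is
attained) lies on the grid. Default resolution 0.01 × 1 × 0.1 mm resolves
the 0.31 mm apertures with 31 samples; `compose_grid` rejects lateral
resolutions coarser than a fifth of the peak width.

## Dosimetric parameters

- **EUD** is the generalized power mean `(Σ vᵢ Dᵢᵃ / Σ vᵢ)^(1/a)`, computed
  with a = −10 over a 1 cm-diameter tumour sphere centred 5 mm deep and
  a = +5 over a concentric 2 cm normal-tissue sphere clipped to the
  modelled depth range. Separability reduces the volumetric mean to a 2-D
  (x, z) mean weighted by the sphere's chord length along y. Doses are
  rescaled by their maximum before exponentiation so a = −10 stays
  numerically stable; a zero dose with a < 0 returns the limit value 0.
- **Volume-average dose** is the arithmetic mean over the field within 1 cm
  depth. For the uniform arm this reproduces the 20 Gy prescription by
  construction of μ. For the array arms the published volume averages
  (which come from measured film profiles) are *not* reproduced by the
  trapezoid model — the published 20.3 % irradiated volume of the 0.31/0.9
  array already disagrees with its 25.6 % geometric duty cycle, indicating
  the measured peaks are effectively narrower than nominal. Quantities that
  depend on the measured profile shape (EUDs, array volume averages) are
  therefore approximate; the published measured table is kept in
  `sfrtkit.design` and is what the cohort generator and association scans
  use as study conditions.
- **Percentage volume directly irradiated** is geometric: the fraction of a
  10 mm tumour disk lying inside peak apertures, positionally averaged for
  the 2 mm array over the maximum-coverage (three peaks) and
  minimum-coverage (two peaks) tumour positions, found by scanning one
  period. A dose-threshold variant was considered and rejected: the
  geometric definition reproduces the design anchors (uniform 100 %, half
  field 50 %) without a threshold choice.
- **PVDR** is the ratio of the surface plateau doses and is undefined
  (None) for the untreated arm.

## Synthetic cohort generator

The generator emulates the study conditions: six arms with n = 8/8/5/6/9/6
(42 animals), pre-treatment volumes lognormal around 566 mm³ (cv 0.20),
matched-bin randomization (sort by volume, cut into bins of six, draw arms
without replacement within each bin, skipping exhausted quotas), visits
every 3 days to day 30, and a day-17 snapshot.

**Growth and kill.** Tumour volume grows exponentially at 0.30 /day
(per-animal lognormal spread, cv 0.08). ln 2/0.30 ≈ 2.3-day doubling puts
every untreated animal past the 2.5 cm sphere-equivalent endpoint
(8 181 mm³) by the day-15 visit, matching the reported untreated outcome
(no survivors at day 17). Radiation rescales the clonogenic compartment by
the linear-quadratic surviving fraction `exp(−αD − βD²)` with D = tumour
EUD (α = 0.30 /Gy, β = 0.015 /Gy², α/β = 20 Gy — a fast-growing,
radiosensitive sarcoma); the surviving compartment regrows after a 3-day
lag while the killed compartment clears at 0.10 /day. These defaults
reproduce the narrative ordering (uniform arm best tumour control,
untreated worst, 50 Gy minibeam near-complete control) without fitting any
per-animal data. A `voxelwise` kill link (LQ survival averaged over the
modelled tumour dose distribution) is available for sensitivity studies.

**Endpoints.** The euthanasia decision replays the monitoring protocol on
the *recorded* (noise-bearing) measurements at scheduled visits only:
sphere-equivalent diameter ≥ 2.5 cm or measured-weight loss > 15 % from
baseline. Event times are therefore visit-aligned, as in the real design,
and no emitted record can violate the endpoint rules on replay.

**Body weight.** Net weight follows
`w(t) = w₀(1 + 0.003·t − 0.005·D_valley·k(t))` with
`k(t) = (t/10)·e^(1−t/10)` peaking at day 10 — a transient
gastro-intestinal-like toxicity proportional to valley dose (the parameter
the toxicity scan is designed to detect). At 20.8 Gy valley dose this gives
a ~5 % net loss at day 17 with recovery after week three; at minibeam
valley doses the gain term dominates. Measured weight adds the tumour mass
at 1 g/cm³.

**Hazard-link mode.** For estimator ground-truth recovery the generator can
instead draw continuous exponential event times with
`rate = 0.08 · exp(−0.15 · tumour EUD)` per day. Times are continuous, not
visit-aligned, deliberately: discretizing onto the 3-day visit grid
attenuates the recovered coefficient through heavy ties and would test the
discretization rather than the estimator.

**What passing tests do not show.** The generator has no immune or
vascular response, no inter-animal correlation, no tumour-shape anisotropy
(the 2.5 cm rule uses the sphere-equivalent diameter), and its growth/kill
parameters are calibrated to narrative facts, not fitted to the study's
per-animal data. Recovery and calibration results demonstrate the
*pipeline's* correctness on data with known structure, not fidelity to the
biological variance of the real cohort.

## Statistical estimators

Implemented directly (reference implementations are used only as test
oracles):

- **Kaplan–Meier** product-limit curve with at-risk and event counts.
- **Logrank (Mantel–Haenszel)**, two groups, hypergeometric variance,
  df = 1. On tie-free data it equals the Cox score test with a binary
  indicator exactly (with ties the hypergeometric factor (n−d)/(n−1)
  differs from the Breslow score variance — the equivalence test uses
  continuous times).
- **Univariate Cox PH**: Newton–Raphson from β = 0 on the partial
  likelihood, |Δβ| < 1e−9, ≤ 50 iterations; Breslow ties by default (events
  fall on shared visit days, and the study's tie convention is unstated),
  Efron available; Wald z and 95 % CI at 1.96·se, plus LRT and score tests.
  Non-convergence (monotone likelihood/separation) raises a warning with
  `converged_ = False`; constant covariates and information-free risk sets
  are errors.
- **Univariate OLS** in closed form with F = t² on (1, n−2) df and R² equal
  to the squared Pearson correlation; **Pearson r** by the product-moment
  formula, erroring on constant input.
- Significance stars: * p<0.05, ** p<0.01, *** p<0.001; p-values two-sided
  from the normal (Wald) and χ² (LRT/score/logrank) references.

## Association pipeline

Day-17 survival is the simple proportion of the initial arm size alive past
day 17 (not a KM estimate), and the snapshot uses each animal's last visit
at or before day 17. Arm-level survival regressions include the untreated
arm with all-zero dosimetry for every parameter except PVDR (undefined
there): with six arms that design reproduces the published F = (n−2)R²/(1−R²)
pairs at df = (1, 4), and with five arms the published PVDR pair at
df = (1, 3). The Cox scan runs per animal (each inheriting its arm's
parameter values) and sorts by |z|; the body-weight scan replaces tumour
EUD with tissue EUD. The correlation matrix is computed over the treated
arms, where PVDR is defined. No multiple-testing correction is applied
across the eight-parameter scans — stars are per-parameter, which is a
caveat, not an oversight.

QC: animals whose measured treated-area fraction deviates from the arm's
nominal value by more than 5 percentage points (strict inequality) are
excluded and logged; animals without a measurement are retained with a
report entry.

## Known limitations and open points

- The trapezoid/exponential dose model reproduces the construction-anchored
  published entries exactly (peak/valley doses, widths, PVDR, open-field
  volume average) but only approximates measurement-derived ones (EUDs,
  array volume averages, film-based irradiated fractions). The published
  measured table is used wherever the analysis needs the study's actual
  conditions.
- With valley dose and tumour EUD correlated at 0.99 across this design,
  the Wald |z| ranking of the Cox scan cannot reliably identify which of
  the two generated the hazard: simulation shows the non-generating member
  of the pair can systematically attain the larger |z| (the likelihood
  ratio orders them correctly asymptotically). Conclusions should treat
  the pair as one statistical signal — which is how the ranking behaves in
  the published scan as well.
- Test problem sizes (e.g. 200 replicates at n = 500 for recovery, 100
  seeded cohorts for calibration) are the package's chosen trade-off
  between statistical resolution and a test suite that runs in minutes on
  one CPU.
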