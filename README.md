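# sfrtkit

Dosimetry and dose–response association analysis for spatially fractionated
radiotherapy (SFRT: GRID and minibeam) small-animal studies.

SFRT delivers intentionally inhomogeneous dose — alternating high-dose
*peaks* and low-dose *valleys* — and its dosimetry therefore cannot be
summarized by a single prescription number. `sfrtkit` implements the
analysis chain used to ask which SFRT dosimetric parameter actually tracks
treatment response in a six-arm rat fibrosarcoma design (uniform field,
half-field, 2 mm planar beam array, 0.31 mm minibeam array at two dose
levels, and an untreated control):

1. **Dose model** — separable parametric fields, `D(x, y, z) =
   L(x) · e^(−μz)`, with trapezoidal lateral peak/valley profiles anchored
   to the measured surface doses and an effective exponential depth dose
   whose μ is calibrated from the open-field surface (20.8 Gy) /
   volume-average (20 Gy over 1 cm) pair.
2. **Dosimetric parameters** — the nine per-arm summaries: peak and valley
   surface dose, peak and valley width, PVDR (= D_peak/D_valley),
   volume-average dose over the 1 cm tumour depth, percentage of the tumour
   cross-section directly irradiated (with min/max positional averaging for
   the 2 mm array), and the two equivalent uniform doses

   EUD_a = (Σᵢ vᵢ Dᵢᵃ)^(1/a),

   with a = −10 over a 1 cm tumour sphere (cold spots dominate) and a = +5
   over a concentric 2 cm normal-tissue sphere (hot spots dominate).
3. **Synthetic cohorts** — matched-bin randomization on pre-treatment
   volume, exponential tumour growth with linear-quadratic radiation kill
   linked to tumour EUD, every-third-day visits to day 30, euthanasia at
   2.5 cm sphere-equivalent diameter or >15 % weight loss, and a
   valley-dose-proportional body-weight toxicity term. Every cohort carries
   its ground-truth parameters for estimator-recovery tests.
4. **Statistics, implemented from first principles** — Kaplan–Meier,
   Mantel–Haenszel logrank, univariate Cox proportional hazards
   (Newton–Raphson on the partial likelihood, Breslow/Efron ties, with
   Wald/LRT/score tests), univariate OLS with the F = (n−2)R²/(1−R²)
   identity, and Pearson correlation. `lifelines`/`statsmodels` appear only
   as independent oracles in the test suite.
5. **Association pipeline** — QC exclusion on treated-area deviation >5
   percentage points, the day-17 snapshot (survival proportion; net body
   weight = measured weight − tumour weight at 1 g/cm³), arm-level survival
   regressions, the per-animal univariate Cox scan sorted by |z|, the
   body-weight regression scan (tissue EUD replacing tumour EUD), and the
   cross-correlation matrix of the eight dosimetric parameters.

## Worked example

```sh
sfrtkit simulate-cohort --seed 1 --out cohort.csv
sfrtkit analyze --cohort cohort.csv --out bundle
```

The day-17 snapshot of that seed (`bundle/day17_snapshot.csv`):

```
               pct_survival  mean_net_weight_change  n_alive
20GyHalfSFRT           60.0                0.023798        3
20GyUniformRT         100.0               -0.055508        8
20Gy2mmSFRT           100.0                0.019565        6
Untreated               0.0                     NaN        0
20GySFRT              100.0                0.019919        9
50GySFRT              100.0               -0.028792        6
```

Every untreated animal reaches the tumour-burden endpoint before day 17
(0 % survival), the uniform arm controls all tumours but is the only arm
losing net body weight (−5.6 %), and the SFRT arms sit in between — the
qualitative pattern the generator is calibrated to. The Cox scan
(`bundle/coxph_scan.csv`, top rows) ranks the parameters by |z|:

```
parameter     estimate   se       hazard_ratio  z       p          stars
valley_dose   -0.436     0.093    0.647         -4.70   2.5e-06    ***
tumor_eud     -0.586     0.128    0.556         -4.56   5.0e-06    ***
vol_avg_dose  -0.173     0.041    0.841         -4.23   2.3e-05    ***
```

A hazard ratio of 0.647 per Gy valley dose means each additional Gy in the
coldest part of the tumour lowers the instantaneous euthanasia risk by
~35 % in this synthetic cohort; valley dose and tumour EUD (r = 0.99 across
the design) dominate the scan, while peak dose ranks last — the central
finding the analysis is built to expose.

## Layout

- `sfrtkit.dose` — beam patterns, depth dose, grid composition, arm presets
- `sfrtkit.metrics` — EUD, PVDR, volume-average dose, coverage, widths
- `sfrtkit.design` — the published six-arm design constants
- `sfrtkit.cohort` — synthetic cohort generator with ground truth
- `sfrtkit.stats` — KM / logrank / Cox / OLS / Pearson (scikit-learn-style)
- `sfrtkit.pipeline` — QC, day-17 snapshot, association scans, report bundle
- `sfrtkit.io`, `sfrtkit.cli` — CSV/YAML formats and the `sfrtkit` CLI

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
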