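# lge-zmap

Quantitative, scanner-independent analysis of late-gadolinium-enhancement
(LGE) cardiac MR for separating **cardiac sarcoidosis (CS)** from
**dilated cardiomyopathy (DCM)**.

Visual LGE reading is subjective, and raw signal intensities are not
comparable across scanners, contrast dose or coil settings.  `lge-zmap`
standardizes each patient's LGE intensities against their own left
ventricle and analyses *where* in the wall the signal concentrates:

1. **Partition.**  The LV myocardium is divided into the AHA 17 segments
   (grouped into anterior / lateral / inferior / septal walls) and nine
   equally spaced transmural layers at 10–90 % of wall thickness
   (sub-endocardial 10–30 %, mid-wall 40–60 %, sub-epicardial 70–90 %).
   In the septum the wall borders the RV cavity, so the septal
   "sub-epicardial" layers are the **RV-side sub-endocardium**.
2. **Standardize.**  Per patient, every segment-layer mean intensity *x*
   becomes a z-score *z* = (*x* − *μ*)/*σ*, with *μ*, *σ* taken over all
   non-excluded cells of the whole LV.  z-maps are invariant to any
   per-patient affine intensity rescaling.
3. **Characterize.**  Tissue classes by fraction of maximal signal
   intensity: healthy < 40 %, border zone 40–60 %, core > 60 %.
4. **Compare.**  Linear mixed models
   *y* = *α* + *β*·I(CS) + *u*(patient) + *v*(layer) + *ε*
   with crossed random intercepts, fit by REML, for z and tissue
   percentages per wall and per wall × band; LOWESS profiles of z against
   transmural depth.
5. **Classify.**  Per patient, the mean z over the septal RV-endocardial
   third is thresholded at the Youden-optimal point; performance is
   estimated by stratified five-fold cross-validation and converted to
   PPV/NPV at the cohort prevalence.

Cells corrupted by ICD lead/generator artifact are flagged and excluded
from every statistic.  A synthetic-cohort generator (table- and
image-level, with known ground truth) makes the whole pipeline testable
without patient data.

## Worked example

Run the full pipeline on the default synthetic cohort (13 DCM-like
patients with a basal septal mid-wall stripe, 9 CS-like patients with
patchy, depth-weighted septal enhancement):

```sh
lge-zmap run --seed 7 --out results/
lge-zmap report --results results/
```

which prints

```
done: 22 patients, 28 fits, mean CV AUC 0.900
lge-zmap 0.1.0 run, seed 7, config 4b03a6ae5bc9ba44
mean CV AUC 0.900 +/- 0.149 z units; threshold 0.20; PPV 0.78, NPV 0.81
```

`results/regression_battery.csv` holds the mixed-model contrasts
(β = CS − DCM).  For this cohort the septal rows read:

| outcome | region          | β     | 95 % CI         | p     | n    |
|---------|-----------------|-------|-----------------|-------|------|
| z       | septal          | 0.181 | (0.044, 0.319)  | 0.010 | 990  |
| z       | septal:sub_epi  | 0.371 | (0.138, 0.604)  | 0.002 | 330  |

i.e. the CS group runs 0.18 z units hotter across the whole septum and
0.37 z units hotter in the RV-endocardial third — the generator's planted
geography, recovered with the denominators expected for 22 patients with
no exclusions (5 segments × 9 layers × 22 = 990; 5 × 3 × 22 = 330).
`results/lowess_septal.csv` contains the per-group LOWESS depth profiles,
and `results/cv_report.json` the per-fold AUCs, the Youden threshold and
the predictive values.

Individual stages are available as `lge-zmap simulate`, `segment`
(image stack + contours → segment-layer table), `zscore`, `analyze` and
`classify`; see `lge-zmap COMMAND --help`.

## Layout

- `src/lge_zmap/synthgen.py` — synthetic cohorts and image stacks with ground truth
- `src/lge_zmap/geometry.py` — AHA segments, transmural layers, pixel aggregation
- `src/lge_zmap/intensity.py` — tissue thresholds, z-score standardization
- `src/lge_zmap/stats.py` — mixed models, regression battery, LOWESS
- `src/lge_zmap/classify.py` — ROC, Youden threshold, cross-validation, PPV/NPV
- `src/lge_zmap/io.py` / `cli.py` — formats, summaries, pipeline driver, CLI

See `docs/methods.md` for the modelling choices and their rationale.
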