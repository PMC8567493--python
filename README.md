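# ftirbone

Bone-quality analysis for FTIR imaging of trabecular bone: spectral-map
feature extraction, and boosted-linear models relating bone quality to
bisphosphonate treatment duration and low-energy fracture.

Long-term antiresorptive treatment changes bone at the mineral and matrix
level — carbonate substitution into apatite (CPR), mineral-to-matrix ratio
(MMR), crystallinity, collagen cross-link maturity (XLR) — in ways that DXA
bone-mineral density does not capture.  This package implements, as a
tested reusable pipeline, the analysis that asks two questions of a
biopsy cohort:

1. **At which treatment duration does bone quality change regime?**
   Duration is dichotomised at candidate cutpoints c ∈ {5,…,9} years and a
   classifier predicts the period from 44 infrared features (per parameter:
   overall mean/SD plus low/medium/high category area fractions and
   area-normalised means/SDs), 12 histomorphometric parameters and patient
   covariates.  The cutpoint with maximal cross-validated AUC is selected.
2. **What drives low-energy fracture?**  The same machinery models the
   fracture flag, comparing feature sets with duration entering
   continuously or categorically, and ranks signed standardised
   coefficients, retaining |c| > 0.2.

Class imbalance is handled by repeated random down-sampling to a balanced
set; features are reduced by mRMR (minimum redundancy / maximum relevance)
inside each training fold; the classifier is XGBoost with linear base
learners and L1/L2 regularisation, so aggregate per-feature linear
coefficients exist.  Because the patient data behind the original analysis
are not public, the package includes a first-class synthetic-cohort
generator (`ftirbone.synthetic`) that plants a known change-point and
fracture mechanism — every downstream claim is testable against that
ground truth.  See `docs/methods.md` for the model details and the
generator's assumptions.

## Worked example

```python
from ftirbone import GeneratorConfig, DurationModel, simulate_cohort
from ftirbone.fracture import fracture_importances

cohort, truth, thresholds = simulate_cohort(GeneratorConfig(n_patients=200), seed=1)
res = DurationModel(cohort, n_repeats=6, cv_folds=4).fit(seed=1)
print(res.summary())
```

```
Duration model (boosted linear classifier, repeated balanced CV)
  feature set: ir_histo_bmi
  repeats: 6, folds: 4, seed: 1
  selected cutpoint: 8 years (AUC = 1.00)

duration_categories  cutpoint_years   auc  accuracy  ...
     1.1–5 and 6–14               5 0.593     0.569
     1.1–6 and 7–14               6 0.707     0.664
     1.1–7 and 8–14               7 0.791     0.758
     1.1–8 and 9–14               8 0.999     0.969
    1.1–9 and 10–14               9 0.991     0.990
```

The sweep recovers the generator's planted 8-year change-point: AUC rises
as the candidate cutpoint approaches the regime change and peaks exactly at
it.  (The near-perfect AUC reflects the deliberately strong planted
effects; on real cohorts separability is far lower.)  The fracture model's
retained coefficients on the same cohort:

```python
imp = fracture_importances(cohort, spec="full", n_repeats=6, seed=1)
print(imp[imp.retained].round(3).to_string(index=False))
```

```
        feature  coefficient  retained
 duration_years        0.476      True
cpr_low_norm_sd       -0.208      True
```

Continuous treatment duration ranks first with a positive sign (longer
treatment, higher fracture odds); the second retained feature is a
carbonate-substitution heterogeneity feature, consistent with the planted
mineral mechanism.  Hip BMD — a candidate feature — is *not* retained,
matching the generator's fracture mechanism, which excludes it.

## Command line

```sh
ftirbone all -o out/ --seed 1          # simulate → extract → features → models
ftirbone report -o out/                # print the evaluation grids
```

Stages can also run individually (`simulate`, `extract`, `features`,
`duration`, `fracture`) against a shared output directory, configured by a
YAML file (`-c config.yaml`) with sections `generator`, `bands`, `booster`
and top-level evaluation settings.  Spectral maps travel in an HDF5
container (`/wavenumbers`, `/samples/<id>/absorbance`, `/samples/<id>/mask`);
tables are CSV stamped with the configuration hash.

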