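# pecg-ira

Recovering diagnostic-quality 10-s 12-lead ECG from compressed paper-ECG
printouts and localizing the infarct-related artery (IRA) in acute
myocardial infarction.

## The problem

Pre-hospital ECGs are still overwhelmingly printed on paper in the
standard 3×4 simultaneous-lead format: each of the twelve leads is
visible for only 2.5 s (four successive 2.5-s columns of one continuous
10-s recording), plus a full 10-s rhythm strip of a single lead (usually
lead II). A 2.5-s glimpse per lead is too short to compute statistically
stable vectorcardiographic features, which is what a classifier needs to
tell *which* coronary artery — left anterior descending (LAD), left
circumflex (LCX), right coronary artery (RCA), or not discernible (E) —
is occluded. This package implements the full chain from a scanned paper
page to an artery call:

1. **Digitization** — grid removal by color thresholding and column-wise
   pixel tracing, calibrated by a three-point frame (1 mV ≙ 10 mm,
   200 ms ≙ 5 mm at 25 mm/s).
2. **Poincaré-ensemble Karhunen–Loève reconstruction** — the observed
   2.5-s segment is delay-embedded (Takens), cut into near-periodic beat
   ensembles at the crossings of a Poincaré section placed on the R-wave
   upstroke, and expanded in the eigenbasis of the ensemble covariance,
   `g(t) = Σᵢ αᵢ φᵢ(t)`, truncated at 95 % of total variance. The
   missing 7.5 s are synthesized by predicting each beat's coefficients
   from the rhythm lead's beats (a least-squares map fitted on the
   overlap window) and placing the beats so their R-peaks coincide with
   the rhythm lead's R-peak times. Quality is measured by the
   residual-energy statistic `R² = 1 − Σ(rec−meas)²/Σ meas²`.
3. **VCG transform** — the reconstructed 12 leads map to the 3-D cardiac
   dipole (X, Y, Z) through the inverse Dower matrix (configurable).
4. **Octant random-walk features** — the dipole trajectory is
   discretized into the 8 Cartesian octants; the walk over octants and
   its directed weighted transition network give 161 named features in
   four groups: local octant statistics (48), residence/sojourn (12),
   arrival/departure rates (16), network topology (85).
5. **Selection and balancing** — PCA-contribution weights
   `w_k = Σᵢ βᵢ c²ₖᵢ` over the components explaining 80 % of variance,
   Gini-importance ranking, Borderline-SMOTE class balancing.
6. **Hierarchical localization** — four binary classifiers mimicking an
   angiography catheter's path: HC vs MI, E vs localizable, left (LAD,
   LCX) vs RCA, LAD vs LCX, each using any of CART / SVM / KNN / NN /
   BET base models.

Because clinical paper archives and angiography labels are not
distributable, the package ships a first-class synthetic generator: a
rotating-dipole, sum-of-Gaussians (ECGSYN-style) beat model with
RR jitter whose disease classes implant an electrical-axis rotation of
20–90°, an ST-segment shift, and T-wave inversion. Every stage is
validated end-to-end against that generator's ground truth.

## Worked example

```python
import numpy as np
from pecg_ira import (
    make_cohort, mask_to_paper_layout, reconstruct_record, rsquared,
    ecg_to_vcg, extract_all, OctantFeatureExtractor, cross_validate,
)

# 1. simulate a labeled cohort (20 records per class)
cohort = make_cohort({"HC": 20, "E": 20, "LAD": 20, "LCX": 20, "RCA": 20}, seed=7)

# 2. reduce one record to its paper-ECG view and reconstruct it
ecg, vcg_truth, label = cohort.records[0]
paper = mask_to_paper_layout(ecg, reference_lead="II")
recon, report = reconstruct_record(paper)
n = int(10 * ecg.fs)
for lead in ("I", "aVL", "V2", "V5"):
    print(f"{lead:>3}: R2 = {rsquared(recon.leads[lead], ecg.leads[lead][:n]):.3f}")

# 3. octant features from the reconstructed VCG
features = extract_all(ecg_to_vcg(recon))
print("features:", len(features), "| Oct1Var =", round(features['Oct1Var'], 4),
      "| MeanTran =", round(features['MeanTran'], 1), "transitions/s")

# 4. cross-validated artery localization on the whole cohort
X = OctantFeatureExtractor().fit_transform([v for _, v, _ in cohort.records])
report = cross_validate(X, np.array(cohort.labels), folds=10, seed=7)
print(report.summary().to_string(index=False))
```

prints

```
  I: R2 = 0.973
aVL: R2 = 0.910
 V2: R2 = 0.976
 V5: R2 = 0.989
features: 161 | Oct1Var = 0.0387 | MeanTran = 181.3 transitions/s
level  accuracy_mean  accuracy_sd
   L1          100.0          0.0
   L2          100.0          0.0
   L3          100.0          0.0
   L4          100.0          0.0
```

The per-lead R² values say how much of the measured signal's energy the
reconstruction recovers after 7.5 s of each lead were hidden (aVL is the
lowest-amplitude lead, hence the smallest value). The four accuracies
are stratified 10-fold cross-validation means for the four hierarchy
levels (HC vs MI, E vs localizable, left vs RCA, LAD vs LCX) on the
synthetic cohort, where the implanted class morphology is fully
recoverable.

A `pecg-ira` umbrella command exposes the same stages from the shell
(`simulate`, `digitize`, `reconstruct`, `to-vcg`, `features`, `select`,
`evaluate`); see `pecg-ira --help`.

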