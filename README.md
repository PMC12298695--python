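# herbfp

Chemometric screening of powdered plant-food supplements for regulated plants,
from full-run LC-MS fingerprints.

Regulated or forbidden botanicals (e.g. slimming plants) are often added to
supplement powders without declaration. Because the products are pulverized
blends, classical botanical identification fails; instead, the whole LC-MS
chromatogram — at each time point a summed intensity and a base-peak *m/z* —
is used as a holistic fingerprint and classified. `herbfp` implements that
workflow end to end for laboratories and method developers:

1. **Calibration design** — *triturations*: a certified reference plant mixed
   into blank supplement matrices at mass ratios 1/20, 1/15, 1/10, 1/5 and
   1/2. With 11 blank matrices this gives 55 known positives, 11 known
   negatives and 1 pure reference = 67 samples per target plant.
2. **Cube assembly** — per-sample `(time, m/z, intensity)` exports are
   interpolated onto a common grid and stacked into a *timepoints × 2 × samples*
   cube, restricted to the 3–10 min fingerprint region, then unfolded into a
   samples × (2 × timepoints) matrix (intensity features first, then mass).
3. **Alignment** — retention-time drift between runs is removed by a coarse
   cross-correlation lag (sub-sample, parabolic refinement) followed by
   **correlation optimized warping** (COW): segment boundaries move within a
   slack budget, and dynamic programming finds the warp maximizing the summed
   segment-wise Pearson correlation with a reference chromatogram.
4. **Modeling** — the matrix is pretreated (Savitzky–Golay derivatives, SNV,
   autoscaling/mean centering), split 75/25 by the deterministic **duplex**
   algorithm, compressed by PLS fitted on training rows, and classified by
   **PLS-DA**: regression of class codes (1 = target present, 2 = absent) on
   PLS factors, thresholded at 1.5. Model complexity *A* ∈ 1..30 is the
   smallest factor count maximizing the 10-fold cross-validated correct
   classification rate (ccr%). Per-feature influence is reported as **VIP**
   scores (mean squared VIP = 1).
5. **Fusion** — a second detector block over the same samples (e.g. DAD) can
   be combined mid-level (per-block PCA scores) or high-level (per-block PLS
   scores), each block scaled to equal total variance, before PLS-DA.
6. **Screening** — unknowns are pushed through each stored per-plant model and
   reported "Present"/"—" with discrepancy flags against label claims.

No public raw data exists for such studies, so the package ships a
first-class synthetic study generator (`herbfp.synthetic`) that reproduces the
statistical structure the analysis assumes — Gaussian-peak chromatograms with
shared excipient and system peaks, heteroscedastic detector noise, injection
variability, run-level retention shifts, and a base-peak mass channel with a
peak-picker detection limit. Every stage is therefore testable offline.

## Worked example

```python
import herbfp

study = herbfp.generate_study()            # 55 triturations + 11 blanks + 1 reference
model, report = herbfp.train_model(study)

print(f"preprocessing : {report.preprocessing_label}")
print(f"PLS factors   : {report.chosen_factors}")
print(f"ccr% CV       : {report.cv.ccr_pct} ({len(report.cv.misclassified)}/{report.cv.n} misclassified)")
print(f"ccr% modeling : {report.calibration.ccr_pct}")
print(f"ccr% test     : {report.test.ccr_pct} ({len(report.test.misclassified)}/{report.test.n} misclassified)")
print(f"test confusion: TP {report.test.tp}  FP {report.test.fp}  TN {report.test.tn}  FN {report.test.fn}")
```

prints

```
preprocessing : 1st derivative (intensity)
PLS factors   : 1
ccr% CV       : 100 (0/50 misclassified)
ccr% modeling : 100
ccr% test     : 100 (0/17 misclassified)
test confusion: TP 12  FP 0  TN 5  FN 0
```

Reading: cross-validation of the 50-sample duplex training set, resubstitution
("modeling") and the 17-sample external test set all classify every sample
correctly; the external test held 12 positives and 5 blanks. Attenuate the
target signature (`GeneratorConfig(signal_scale=...)`) and the lowest-ratio
triturations are the first to be missed — the detection-limited regime such
screening methods operate in.

The same workflow is available from the shell:

```bash
herbfp generate --out study/ --seed 0
herbfp train --data study/ --model target.npz --report report.csv
herbfp screen --model target.npz --unknowns seized_samples/ --out verdicts.csv
herbfp fuse --block-a ms_block/ --block-b dad_block/ --level high --out comparison.csv
```

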