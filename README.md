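# pvfield

Single-beat discrimination of pulmonary-vein **nearfield** (NF) from atrial
**farfield** (FF) bipolar voltage electrograms (BVE) recorded on a circular
mapping catheter (CMC).

## The problem

Confirming pulmonary vein isolation (PVI) after catheter ablation of atrial
fibrillation requires deciding whether the signal seen on the CMC still
contains a *local* PV potential or is only the superimposed farfield of the
surrounding atrium.  When the two components overlap in time — common with
cryoballoon "single-shot" ablation, where no second catheter is available
for pacing manoeuvres — that call is hard even for experienced
electrophysiologists.  `pvfield` implements an automatic classifier that
makes the call from a **single beat**, for EP engineers and researchers who
process intracardiac recordings offline.

## The method

Each annotated beat (onset–offset window on an 8-bipole, 2 kHz recording,
band-passed 30–300 Hz with a 50 Hz notch) is reduced to six features:

| feature | definition |
|---|---|
| `p_hf` | power in the **150–300 Hz** band of a 35 ms window slid across the beat, zero-padded to a 10 Hz DFT grid; the maximum over windows, on the bipole where that maximum is largest |
| `p_lf` | 0–150 Hz power at the same window position |
| `p_hf_rel` | `p_hf / (p_lf + p_hf)` |
| `p_hf_neighbor_ratio` | `p_hf` of the selected bipole over its two ring neighbours (larger of the two ratios) — local sources decay steeply across the loop |
| `v_max` | peak-to-peak amplitude in the beat window (mV) |
| `slew_rate_prop` | fraction of beat samples with \|dV/dt\| > 0.15 V/s |

The physics behind the split: a local NF deflection is "sharp" (energy above
150 Hz, steep slew, fast spatial decay around the loop), the atrial FF is
broad and low-frequency and nearly identical on all bipoles.  Features are
log-transformed where skewed and z-scored, then fed to one of four
classifier families (decision tree, LDA, linear SVM, KNN).  Validation is
patient-level: 25 % of patients held out, 4-fold grouped cross-validation on
the rest, bootstrap confidence intervals for the ROC/AUC.  The binary target
counts `PV-NF` and `combined` beats as nearfield-positive.

A synthetic generator (`pvfield.synthetic`) emulates CMC recordings with
Gabor-atom beats of the three classes, spatial decay across the eight
bipoles, freeze-cycle delay/disappearance sequences, mains interference and
noise — so the entire pipeline is testable without clinical data.

## Worked example

```python
from pvfield.pipeline import synthetic_feature_table
from pvfield.classify import ValidationScheme, run_validation

table = synthetic_feature_table("overlap_heavy", seed=1, n_patients=28,
                                beats_per_patient=12)
print(table[["p_hf", "v_max", "label"]].groupby("label").median().round(3))

report = run_validation(table, algorithm="svm", feature_subset=["p_hf", "v_max"],
                        scheme=ValidationScheme(seed=1, n_boot=1000))
print(report.to_text())
```

prints

```
            p_hf  v_max
label
PV-NF      0.672  0.346
atrial-FF  0.070  0.609
combined   0.331  0.653
algorithm: svm  features: p_hf, v_max
scope: holdout  beats: 64  patients: 28
confusion (nearfield positive): TP=17 FN=11 FP=0 TN=36
accuracy 82.8%  sensitivity 60.7%  specificity 100.0%
cross-validation accuracy 90.5%
AUC 0.953 (0.893 to 0.997, 95% bootstrap CI, n_boot=1000)
  LIPV: 95.5%
  LSPV: 68.8%
  RIPV: 77.8%
  RSPV: 87.5%
```

Reading the output: nearfield-positive beats (`PV-NF`, `combined`) carry an
order of magnitude more high-band power than pure farfield; on this
deliberately hard "overlap-heavy" condition the two-feature SVM classifies
82.8 % of held-out beats correctly, with perfect specificity and the misses
concentrated in weak nearfield beats.  The same run on the default
"separated" condition is essentially perfect.

The same pipeline is available from the shell:

```sh
pvfield simulate --out ds --n-patients 28 --beats-per-patient 12 --seed 1
pvfield extract --dataset ds --out features.csv
pvfield train-eval --features-csv features.csv --out run --algorithm svm \
    --features p_hf,v_max
```

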