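# Methods

This note documents the models, conventions and design choices behind
`pvfield`, in the order data flows through the package.

## Signal model and data contracts

A `Recording` is an ordered set of bipolar channels sampled at a common
rate (clinically 2000 Hz from an octapolar circular mapping catheter,
giving 8 bipoles in a ring).  **Channel order defines loop adjacency**:
neighbours of bipole *i* are *(i−1 mod K)* and *(i+1 mod K)*.  The Achieve
ring-pair wiring is not standardised in our sources, so the package assumes
recording channel order equals loop order; if a recording system emits
channels in another order, reorder them at import.

Beat annotations are half-open sample windows: milliseconds map to samples
as `floor(onset·fs/1000)` inclusive to `ceil(offset·fs/1000)` exclusive,
so adjacent beats never double-count a sample.  Annotation validation
enforces the clinical ontology: after electrical isolation (`phase="after"`)
a nearfield component cannot exist, so `PV-NF` and `combined` labels are
rejected there.

EDF is read through `mne`.  Because no installed backend writes EDF, the
package carries its own minimal single-record EDF writer (16-bit, physical
unit mV); round trips are validated against the independent `mne` reader in
the test suite.  The CSV+JSON fixture dialect stores floats at `%.17g`, so
write→read is bit-exact.

## Preprocessing

The acquisition chain is replicated as a 4th-order Butterworth band-pass
(30–300 Hz) plus a 2nd-order IIR notch (50 Hz, Q = 30), both applied
forward–backward.  Zero phase matters: a causal filter would skew beat
onsets and slew rates, the very morphology the temporal features measure.
Filtering is linear and length-preserving.

Noisy beats are gated on the ratio of baseline RMS (a 50 ms window
immediately before the beat onset, i.e. before the P-wave) to beat RMS.
Defaults: `reference_window_ms = 50`, `ratio_threshold = 0.2`, rejection on
strict inequality.  Whether the clinical gate operated per channel or per
beat is not documented; since feature extraction later retains a single
best bipole, the package rejects a beat only when **every** channel fails
(configurable).  The gate is scale-invariant by construction.

## Spectral features

Band powers come from a zero-padded DFT of a 35 ms rectangular window:
70 samples at 2 kHz padded to `nfft = fs / Δf = 200`, which places bins on
an exact 10 Hz grid.  Power in a band is the sum of squared one-sided bin
magnitudes over the band, divided by the number of *un-padded* samples.
Numerical conventions, each tested:

* **Band edges**: LF = [0, 150) Hz, HF = [150, 300] Hz — the 150 Hz bin
  belongs to the high band, the 300 Hz bin is included.  Some convention is
  required for on-bin edges; this one keeps "150 to 300 Hz" inclusive.
* **Window sliding**: 5 ms steps, windows fully inside the beat; a beat
  shorter than 35 ms yields a single zero-padded window.  The channel-level
  `P_HF` aggregates windows by **max**, catching the sharp NF transient
  wherever it sits inside the beat.
* **Bipole selection**: the channel with the highest channel-level `P_HF`
  is retained (ties → lowest index); `p_lf` and `p_hf_rel` are read at the
  maximising window of that channel.  Whether the reference analysis took
  `P_LF` at the same window or aggregated separately is unstated; the
  package fixes "same window", which keeps `p_hf_rel = p_hf/(p_lf+p_hf)` an
  exact identity.
* **Neighbour ratio**: channel-level `P_HF` of the selected bipole over
  each circular neighbour, keeping the larger ratio.  Exactly-zero
  neighbour powers (possible on noiseless synthetic channels) are floored
  at 1e−12 mV² to keep the ratio finite; the flag is recorded.
* Rectangular taper by default (only a window *width* is specified
  anywhere); Hann is available via `SpectralConfig(taper="hann")`.

## Temporal features

`v_max` is peak-to-peak (max − min) within the beat window on the selected
bipole — the EP-lab convention for bipolar amplitude ("amplitude" alone is
ambiguous between peak-to-peak and largest deflection; peak-to-peak is the
choice here).  The derivative uses central differences with one-sided
endpoints, scaled to V/s; `slew_rate_prop` is the fraction of beat samples
with |dV/dt| above 0.15 V/s (the "sharpness" threshold used for nearfield
sensing).  Both features are sign-flip invariant.

## Normalisation and classifiers

Features with |skewness| > 1 on the training sample (band powers and
amplitudes typically qualify) are passed through `log(x + 1e−12)` before
z-scoring; parameters are frozen from training rows only and the transform
is invertible.  Zero-variance features raise an error naming the feature.

Four families are wrapped behind one scikit-learn estimator
(`NearfieldClassifier`): linear SVM (C = 1), LDA with pooled covariance,
KNN (k = 5), decision tree (depth ≤ 4).  Defaults are deliberately plain —
the point of the method is that two simple features suffice, not
hyperparameter search.  The decision score is oriented so larger = more
nearfield-like (signed decision value for SVM/LDA, positive-class fraction
for KNN/tree).  `PV-NF` and `combined` map to the positive class: the
clinical question is *presence* of a nearfield component.

Models persist to JSON as algorithm + hyperparameters + training rows;
loading refits deterministically, which reproduces the exact decision
function for every family without serialising sklearn internals.

## Validation design

Patients — never beats — are the splitting unit: 25 % of patients are held
out (seeded permutation), 4-fold `GroupKFold` cross-validation runs on the
rest, and the reported confusion matrix, per-vein accuracies and ROC come
from the holdout predictions (`scope="holdout"`; `scope="pooled"` adds the
out-of-fold CV predictions, since reports in the literature do not always
say which was used).  The split is asserted structurally: no patient's
beats may straddle the partition.

AUC is the tie-averaged rank (Mann–Whitney) statistic, identical to the
trapezoidal area under the empirical ROC and exact for separable scores.
Confidence intervals are percentile bootstrap over 1000 beat-level
resamples stratified by class (stratification guarantees both classes in
every resample); 95 % level by default.  Forward feature selection is a
greedy wrapper on grouped-CV overall accuracy with a 0.5-percentage-point
stopping improvement and first-wins tie-breaking.

Percentages are reported to 1 decimal place.

## Synthetic data: what it emulates, and what it does not

Each beat is a sum of Gabor atoms (Gaussian-envelope sinusoids, support =
±3σ of the envelope):

| component | centre freq | support | peak amp | ring decay |
|---|---|---|---|---|
| atrial FF | 80 Hz | 70 ms | 0.3 mV | 0.95 / step (from a random reference bipole) |
| PV NF | 220 Hz | 58 ms | 0.5 mV | 0.40 / step (from the active bipole) |

plus white noise (0.02 mV RMS), a common-mode 50 Hz mains component
(0.01 mV), per-beat log-normal gain jitter (σ = 0.35, FF and NF
independent) and duration jitter (σ = 0.12).  In `combined` beats the NF
trails the FF onset by 36 ms, so the annotated window is ≈ 94 ms versus
≈ 70 ms (FF) and ≈ 58 ms (NF) — matching the median-duration ordering of
the three classes in clinical material.  The default class mix is
163 : 83 : 89 (FF : NF : combined) per 335 beats, i.e. 51.3 %
nearfield-positive.  Freeze-cycle simulation strings combined beats with a
linearly growing NF delay and switches to pure FF at the isolation beat.

Amplitudes and noise levels were chosen once so that the default
("separated") condition is learnable but not degenerate: the NF atom sits
clearly above the in-band noise floor, and single-feature `p_hf`
discrimination is near-perfect (AUC ≥ 0.95).  The **overlap-heavy**
condition drops the NF amplitude to 0.1 mV, centres the NF delay at zero
(full temporal superposition) and widens gain jitter to σ = 0.6; this
places single-feature `p_hf` at AUC ≈ 0.87 with holdout accuracy in the
high 70s, where the amplitude feature `v_max` has real work to do — the
regime the two-feature model was designed for.

The generator reproduces the *statistical structure the classifier
exploits* — spectral separation, spatial decay, temporal overlap, class
balance, freeze-cycle sequencing — not cardiac biophysics.  It has no
ventricular farfield, no respiration or catheter-motion artefacts, no
atrial-fibrillation rhythms (sinus rhythm only), no inter-patient anatomy
differences, and its vein labels do not modulate signal morphology (so
per-vein accuracy tables on synthetic data show sampling noise, not the
clinical LSPV/LAA effect).  Passing tests on synthetic data therefore
demonstrate the pipeline's correctness and the features' discriminative
mechanics, not clinical-grade performance.

## Problem sizes and determinism

Test-suite and acceptance runs use 28 patients × 12 beats (336 beats,
≈ the 335-beat reference scale) per difficulty condition; smaller fixtures
are used where only plumbing is under test.  All randomness flows from
explicit seeds through `numpy.random.Generator` substreams (one per
patient, spawned from the master seed), making datasets, feature tables and
reports byte-reproducible; identical seeds yield identical files.

## Known limitations

* Onset/offset delimitation is an input; the package does not detect beats.
* The noise-gate numbers (50 ms window, 0.2 ratio) are package defaults;
  the clinical gate's exact criterion is undocumented.  On the
  overlap-heavy synthetic condition the gate removes ≈ 20 % of beats,
  preferentially weak nearfield ones — a selection effect a clinical
  deployment would need to quantify.
* The linear-SVM score is not a calibrated probability.
* EDF output is plain EDF with one data record; continuous recordings
  longer than ~30 s per file should use the CSV dialect or be segmented.
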