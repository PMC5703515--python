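# oxiscreen

Automated screening for moderate-to-severe obstructive sleep apnea (OSA)
from overnight **portable pulse-oximetry** alone.

In-laboratory polysomnography (PSG) is the diagnostic gold standard for
sleep apnea, but it is scarce, labor-intensive and expensive. A wrist-worn
oximeter recording blood oxygen saturation (SpO₂) at 1 Hz is cheap and works
unattended at the patient's home — if its signal can be turned into a
reliable estimate of the **apnea–hypopnea index (AHI)**, the number of
respiratory events per hour that defines disease severity (≥ 5 mild,
≥ 15 moderate, ≥ 30 severe). `oxiscreen` implements a complete
oximetry-to-AHI pipeline and the statistical apparatus used to validate a
screening test, for sleep clinicians and biomedical-signal researchers who
need a transparent, scriptable implementation. It is relevant both for
otherwise healthy referrals and for patients with COPD, whose chronically
low baseline saturation is often assumed (wrongly, per the validation
design this package follows) to defeat oximetry-based screening.

## The pipeline

1. **Pre-processing.** Probe-off and movement artifacts are removed by three
   rules: zero samples, saturations below 20 %, and sample-to-sample changes
   ≥ 4 %/s. Remaining segments are re-joined, linearly interpolating any
   junction that would itself jump ≥ 4 %/s.
2. **Feature extraction** — 16 features in 4 subsets:
   time-domain moments *M1t–M4t* (mean, variance, skewness, kurtosis of the
   saturation histogram, per non-overlapping 512-sample segment, averaged);
   frequency-domain statistics *M1f–M4f*, median frequency *MF* and spectral
   entropy *SE* of the Welch periodogram (512-sample Hann window, 50 %
   overlap, 1024-point FFT); conventional spectral measures — total power
   *P_T*, and peak amplitude *PA* and relative power *P_R* in the
   0.014–0.033 Hz band where recurrent apneic desaturations live; and
   nonlinear measures — sample entropy *SampEn*, central tendency measure
   *CTM*, and Lempel–Ziv complexity *LZC*.
3. **Feature selection** by the fast correlation-based filter (FCBF):
   features are ranked by symmetrical uncertainty with the reference AHI,
   SU(X,Y) = 2·IG(X,Y) / (H(X)+H(Y)), and a lower-ranked feature *j* is
   discarded when SU(i,j) ≥ SU(j,AHI) for a retained feature *i*.
4. **Regression MLP.** A single-hidden-layer network
   y = Σⱼ ωⱼ·g(Σᵢ ωᵢⱼxᵢ + bⱼ) + b, g = tanh, output clipped to [0, ∞),
   trained by L-BFGS on squared error with weight decay ν‖w‖²; the number of
   hidden neurons N_H and ν are chosen by repeated leave-one-out
   cross-validation scored by the intra-class correlation coefficient (ICC).
   The published per-setting architectures ship as presets
   (`PRESET_LAB`: 9 features, N_H = 12, ν = 1; `PRESET_HOME`: 8 features,
   N_H = 12, ν = 4).
5. **Comparators and evaluation.** Conventional oxygen desaturation indices
   (ODI3/ODI4), CT90 and summary saturations; agreement statistics (ICC with
   95 % CI, Bland–Altman bias and limits of agreement, mountain plots) and
   diagnostic metrics (Se, Sp, PPV, NPV, LR±, accuracy, ROC AUC with
   Hanley–McNeil CI) at the 15 and 30 events/h cutoffs.

A seeded synthetic-recording generator (`oxiscreen.synthetic`) produces
overnight SpO₂ series with a known implanted event rate, COPD-like baselines
and injectable artifacts, so every stage is testable without patient data.

## Worked example

`examples/train_ahi_estimator.py` simulates a 50-subject cohort (true AHI
uniform on 0–60 events/h), runs FCBF and leave-one-out cross-validation of
the MLP, and prints:

```
FCBF selected 5/16 features: M1t, M4t, PA, MF, SampEn
  SU(M1t, AHI) = 0.799
  ...
loo-cv ICC = 0.964 (0.938, 0.979 CI95)
Bland-Altman: bias +0.61 events/h, LoA width 17.89
```

The ICC of 0.964 says the held-out AHI estimates agree almost perfectly
with the implanted event rates; the bias near zero and the ±9 events/h
limits of agreement describe the size of individual estimation errors.
`examples/screen_single_recording.py` does the same for a single corrupted
recording (artifact counts, the 16 features, ODI3/ODI4/CT90), and
`examples/evaluate_screening_test.py` shows the full agreement + diagnostic
report for a per-subject cohort table.

A thin CLI wraps the same API:

```bash
oxiscreen simulate --event-rate 25 --seed 3 --out-dir run/
oxiscreen features run/recording.csv --out-dir run/
oxiscreen indices run/recording.csv
oxiscreen evaluate cohort.csv --estimate-column ahi_ox_lab
```

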