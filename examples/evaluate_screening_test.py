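"""Diagnostic evaluation of an AHI estimator as a screening test.

Builds a per-subject cohort table (reference AHI plus a noisy estimate, as
an at-home screening device would produce), then reports the agreement
(ICC, Bland-Altman, mountain plot) and the diagnostic performance at the
moderate (>= 15 events/h) and severe (>= 30 events/h) cutoffs.
"""

import numpy as np

import oxiscreen as ox

rng = np.random.default_rng(3)
n = 120
ahi_psg = rng.uniform(0, 70, n)
# estimator with mild proportional bias and night-to-night noise
ahi_est = np.clip(1.5 + 0.92 * ahi_psg + rng.normal(0, 6, n), 0, None)

agreement = ox.evaluate_agreement(ahi_psg, ahi_est)
print(f"ICC {agreement.icc:.3f} "
      f"({agreement.icc_ci95[0]:.3f}, {agreement.icc_ci95[1]:.3f} CI95)")
print(f"Bland-Altman bias {agreement.bias:+.2f} events/h, "
      f"LoA [{agreement.loa_low:.1f}, {agreement.loa_high:.1f}], "
      f"width {agreement.loa_width:.1f}")
peak = max(agreement.mountain, key=lambda p: p[1])
print(f"mountain plot peaks at a difference of {peak[0]:+.1f} events/h")

for cutoff in (15.0, 30.0):
    rep = ox.confusion_metrics(ahi_est, ahi_psg, cutoff)
    lr_pos = "NA" if rep.lr_pos is None else f"{rep.lr_pos:.2f}"
    print(f"cutoff {cutoff:.0f}: Se {rep.se:.1f}%  Sp {rep.sp:.1f}%  "
          f"PPV {rep.ppv:.1f}%  NPV {rep.npv:.1f}%  LR+ {lr_pos}  "
          f"LR- {rep.lr_neg:.2f}  Acc {rep.acc:.1f}%")

auc, ci, _ = ox.roc_auc(ahi_est, ahi_psg >= 30)
print(f"AUC (severe) {auc:.3f} ({ci[0]:.3f}, {ci[1]:.3f} CI95)")
print("Se/Sp trade off at each fixed cutoff; the AUC summarizes ranking "
      "performance across all cutoffs.")
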