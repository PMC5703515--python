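"""Agreement and diagnostic-performance statistics for AHI estimators.

Agreement between an estimated and a reference AHI is quantified by the
intra-class correlation coefficient (two-way random effects, absolute
agreement, single measures — ICC(2,1) — by default) and described by
Bland-Altman bias and 95 % limits of agreement and by the mountain plot
(folded empirical CDF of the differences). Diagnostic performance at the
moderate (>= 15 events/h) and severe (>= 30 events/h) cutoffs is reported as
sensitivity, specificity, predictive values, likelihood ratios and accuracy
with 95 % confidence intervals, plus the empirical ROC AUC (Hanley-McNeil
confidence interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sct
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AgreementReport",
    "DiagnosticReport",
    "icc",
    "bland_altman",
    "mountain_plot",
    "confusion_metrics",
    "roc_auc",
    "severity_class",
    "evaluate_agreement",
    "CUTOFF_MODERATE",
    "CUTOFF_SEVERE",
]

CUTOFF_MODERATE = 15.0
CUTOFF_SEVERE = 30.0


@dataclass
class AgreementReport:
    icc: float
    icc_ci95: tuple[float, float]
    icc_variant: str
    bias: float
    loa_low: float
    loa_high: float
    loa_width: float
    mountain: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DiagnosticReport:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    se: float
    sp: float
    ppv: float
    npv: float
    acc: float
    lr_pos: float | None  # None when Sp = 100 % (not defined)
    lr_neg: float | None
    se_ci: tuple[float, float]
    sp_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    acc_ci: tuple[float, float]
    lr_pos_ci: tuple[float, float] | None
    lr_neg_ci: tuple[float, float] | None

    def to_dict(self) -> dict:
        return asdict(self)


def icc(a: np.ndarray, b: np.ndarray, variant: str = "agreement",
        ci: bool = True) -> tuple[float, tuple[float, float]]:
    """Intra-class correlation between two paired measurement series.

    ``variant``: "agreement" -> ICC(2,1), two-way random, absolute agreement;
    "consistency" -> ICC(3,1). The CI uses the McGraw & Wong F-distribution
    method. Requires at least 3 pairs and some between-subject variance.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D arrays")
    n = len(a)
    if n < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    Y = np.column_stack([a, b])
    k = 2
    if np.var(Y) == 0:
        raise ValueError("ICC undefined: no variance in the data")

    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    grand = Y.mean()
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # between-subjects
    msc = ss_cols / (k - 1)          # between-raters
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)  # residual

    if variant == "consistency":
        val = (msr - mse) / (msr + (k - 1) * mse)
    elif variant == "agreement":
        val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")

    if not ci:
        return float(val), (math.nan, math.nan)

    alpha = 0.05
    if variant == "consistency":
        f_obs = msr / mse if mse > 0 else math.inf
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sct.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sct.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + (k - 1))
        hi = (fu - 1) / (fu + (k - 1))
    else:
        # McGraw & Wong (1996) CI for ICC(A,1)
        if mse > 0:
            fj = msc / mse
            a_ = k * val / (n * (1 - val)) if val < 1 else math.inf
            b_ = 1 + k * val * (n - 1) / (n * (1 - val)) if val < 1 else math.inf
            v = (a_ * msc + b_ * mse) ** 2 / (
                (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1)))
            f1 = sct.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sct.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f1 * mse)) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = (n * (f2 * msr - mse)) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr)
        else:
            lo = hi = val
    return float(val), (float(max(lo, -1.0)), float(min(hi, 1.0)))


def bland_altman(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    """Bias, limits of agreement and LoA width for differences b - a."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length arrays with n >= 2")
    d = b - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    return bias, lo, hi, hi - lo


def mountain_plot(differences: np.ndarray) -> list[tuple[float, float]]:
    """Folded empirical CDF of method differences: (difference, folded %-ile).

    The folded percentile is min(p, 100 - p); the curve peaks at the median
    difference, and its spread mirrors the limits of agreement.
    """
    d = np.sort(np.asarray(differences, float))
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 differences")
    p = 100.0 * (np.arange(1, n + 1) - 0.5) / n
    folded = np.minimum(p, 100.0 - p)
    return list(zip(d.tolist(), folded.tolist()))


def _prop_ci(x: int, n: int) -> tuple[float, float]:
    """Wald CI in percent, Wilson when any cell is sparse (< 5)."""
    if n == 0:
        return (math.nan, math.nan)
    method = "normal" if min(x, n - x) >= 5 else "wilson"
    lo, hi = proportion_confint(x, n, alpha=0.05, method=method)
    return (100.0 * lo, 100.0 * hi)


def confusion_metrics(pred_ahi: np.ndarray, true_ahi: np.ndarray,
                      cutoff: float) -> DiagnosticReport:
    """Diagnostic metrics with a subject positive iff AHI >= cutoff."""
    pred = np.asarray(pred_ahi, float)
    true = np.asarray(true_ahi, float)
    if pred.shape != true.shape:
        raise ValueError("prediction/reference length mismatch")
    pp = pred >= cutoff
    tt = true >= cutoff
    tp = int(np.count_nonzero(pp & tt))
    fp = int(np.count_nonzero(pp & ~tt))
    tn = int(np.count_nonzero(~pp & ~tt))
    fn = int(np.count_nonzero(~pp & tt))
    return confusion_metrics_from_counts(tp, fp, tn, fn, cutoff)


def confusion_metrics_from_counts(tp: int, fp: int, tn: int, fn: int,
                                  cutoff: float = math.nan) -> DiagnosticReport:
    """Metrics straight from a 2x2 contingency table."""
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty contingency table")
    pct = lambda x, d: 100.0 * x / d if d > 0 else math.nan
    se = pct(tp, tp + fn)
    sp = pct(tn, tn + fp)
    ppv = pct(tp, tp + fp)
    npv = pct(tn, tn + fn)
    acc = pct(tp + tn, n)

    lr_pos = lr_neg = None
    lr_pos_ci = lr_neg_ci = None
    if tn + fp > 0 and tp + fn > 0:
        se_f, sp_f = se / 100.0, sp / 100.0
        if sp_f < 1.0:
            lr_pos = se_f / (1.0 - sp_f)
            lr_pos_ci = _lr_ci(tp, fn, fp, tn, positive=True)
        if sp_f > 0.0:
            lr_neg = (1.0 - se_f) / sp_f
            lr_neg_ci = _lr_ci(tp, fn, fp, tn, positive=False)

    return DiagnosticReport(
        cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn,
        se=se, sp=sp, ppv=ppv, npv=npv, acc=acc,
        lr_pos=lr_pos, lr_neg=lr_neg,
        se_ci=_prop_ci(tp, tp + fn), sp_ci=_prop_ci(tn, tn + fp),
        ppv_ci=_prop_ci(tp, tp + fp), npv_ci=_prop_ci(tn, tn + fn),
        acc_ci=_prop_ci(tp + tn, n),
        lr_pos_ci=lr_pos_ci, lr_neg_ci=lr_neg_ci,
    )


def _lr_ci(tp: int, fn: int, fp: int, tn: int, positive: bool,
           alpha: float = 0.05) -> tuple[float, float] | None:
    """Log-method CI for likelihood ratios (Simel et al.)."""
    z = sct.norm.ppf(1 - alpha / 2)
    if positive:
        a, b, c, d = tp, tp + fn, fp, fp + tn
    else:
        a, b, c, d = fn, tp + fn, tn, fp + tn
    if a == 0 or c == 0:
        return None
    lr = (a / b) / (c / d)
    se_log = math.sqrt((1 - a / b) / a + (1 - c / d) / c)
    return (lr * math.exp(-z * se_log), lr * math.exp(z * se_log))


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[float, tuple[float, float], np.ndarray]:
    """Empirical (trapezoidal) AUC with Hanley-McNeil CI and the ROC curve.

    Equivalent to the normalized Mann-Whitney U statistic; ties between a
    positive and a negative score contribute 1/2.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC analysis")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))

    # Hanley & McNeil (1982) standard error
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    z = sct.norm.ppf(0.975)
    half = z * math.sqrt(max(var, 0.0))
    ci = (max(auc - half, 0.0), min(auc + half, 1.0))
    return auc, ci, np.column_stack([fpr, tpr])


def severity_class(ahi: float) -> str:
    """Clinical severity category: <5 normal, 5-15 mild, 15-30 moderate, >=30 severe."""
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    if ahi < 5:
        return "normal"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def evaluate_agreement(reference: np.ndarray, estimate: np.ndarray,
                       variant: str = "agreement") -> AgreementReport:
    """Full agreement analysis of an estimated AHI against the reference."""
    val, ci = icc(reference, estimate, variant)
    bias, lo, hi, width = bland_altman(reference, estimate)
    mountain = mountain_plot(np.asarray(estimate, float) - np.asarray(reference, float))
    return AgreementReport(icc=val, icc_ci95=ci, icc_variant=variant,
                           bias=bias, loa_low=lo, loa_high=hi,
                           loa_width=width, mountain=mountain)
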