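"""Agreement, error, and classification statistics for paired attenuation readings.

Implements the evaluation layer used to compare an automated attenuation
method against a reference standard: two-sample Kolmogorov–Smirnov tests,
Bland–Altman 95% limits of agreement, MAE/MSE, Spearman rank correlation,
ICC(2,1) (two-way random effects, absolute agreement, single measures)
with its F-based 95% confidence interval, and threshold-classifier
performance (AUC, sensitivity, specificity) with percentile bootstrap
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from sklearn.metrics import roc_auc_score


@dataclass
class PairedReadings:
    """Per-case attenuation readings from a method and a reference standard."""

    case_ids: list
    method_hu: np.ndarray
    reference_hu: np.ndarray

    def __post_init__(self) -> None:
        self.method_hu = np.asarray(self.method_hu, dtype=np.float64)
        self.reference_hu = np.asarray(self.reference_hu, dtype=np.float64)
        n = len(self.case_ids)
        if not (n == len(self.method_hu) == len(self.reference_hu)):
            raise ValueError("case_ids, method_hu and reference_hu must have equal length")
        if n < 2:
            raise ValueError("need at least 2 paired readings")
        if not (np.isfinite(self.method_hu).all() and np.isfinite(self.reference_hu).all()):
            raise ValueError("readings must be finite")

    @property
    def diffs(self) -> np.ndarray:
        return self.method_hu - self.reference_hu


@dataclass
class AgreementReport:
    ks_statistic: float
    ks_p: float
    mean_diff_hu: float
    loa_low_hu: float
    loa_high_hu: float
    mae: float
    mse: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    spearman_rho: float


@dataclass
class ClassificationReport:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sens_ci: tuple[float, float]
    specificity: float
    spec_ci: tuple[float, float]
    threshold_hu: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_boot: int
    n_degenerate_replicates: int = 0


def ks_compare(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test (asymptotic p-value).

    The statistic is the supremum of the absolute ECDF difference; the
    p-value comes from the classical Kolmogorov limiting distribution
    evaluated at ``sqrt(n*m/(n+m)) * D``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    d = float(stats.ks_2samp(a, b, alternative="two-sided").statistic)
    en = np.sqrt(len(a) * len(b) / (len(a) + len(b)))
    p = float(special.kolmogorov(en * d))
    return d, p


def bland_altman(pairs: PairedReadings) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean ± 1.96 sample SD)."""
    d = pairs.diffs
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd


def error_and_correlation(pairs: PairedReadings) -> tuple[float, float, float]:
    """MAE, MSE, and Spearman rank correlation of method vs reference."""
    d = pairs.diffs
    mae = float(np.abs(d).mean())
    mse = float((d ** 2).mean())
    rho = float(stats.spearmanr(pairs.method_hu, pairs.reference_hu).statistic)
    return mae, mse, rho


def icc_absolute_single(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is an n-subjects x k-raters matrix with no missing cells.
    The confidence interval uses the F-distribution method of McGraw & Wong
    with Satterthwaite degrees of freedom.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D (subjects x raters) matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("ratings must be finite (no missing cells)")
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    if ss_total < 1e-12:
        raise ValueError("undefined ICC: ratings matrix has zero variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ss_total - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # Satterthwaite df for the rater/error mixture, then F-based bounds
    if mse > 0:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = icc
    return float(icc), float(lower), float(upper)


def agreement_report(pairs: PairedReadings) -> AgreementReport:
    """Full agreement analysis of method vs reference readings."""
    ks_stat, ks_p = ks_compare(pairs.method_hu, pairs.reference_hu)
    mean_diff, lo, hi = bland_altman(pairs)
    mae, mse, rho = error_and_correlation(pairs)
    icc, ci_lo, ci_hi = icc_absolute_single(
        np.column_stack([pairs.method_hu, pairs.reference_hu])
    )
    return AgreementReport(
        ks_statistic=ks_stat, ks_p=ks_p,
        mean_diff_hu=mean_diff, loa_low_hu=lo, loa_high_hu=hi,
        mae=mae, mse=mse,
        icc=icc, icc_ci_low=ci_lo, icc_ci_high=ci_hi,
        spearman_rho=rho,
    )


def classification_performance(
    scores_hu, labels, threshold_hu: float = 40.0, n_boot: int = 1000,
    seed: int | None = None,
) -> ClassificationReport:
    """Threshold-classifier performance with percentile bootstrap CIs.

    A case is predicted positive (steatosis) iff its attenuation score is
    strictly below the threshold; the AUC treats lower attenuation as more
    positive (rank/Mann–Whitney formulation via the ROC curve on the
    negated score). Bootstrap replicates that lose one of the classes are
    skipped and counted.
    """
    scores = np.asarray(scores_hu, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    def _point(s, y):
        pred = s < threshold_hu
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        tn = int((~pred & ~y).sum())
        fn = int((~pred & y).sum())
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        auc = float(roc_auc_score(y, -s))
        return auc, sens, spec, (tp, fp, tn, fn)

    auc, sens, spec, (tp, fp, tn, fn) = _point(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    boots = []
    degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        y = labels[idx]
        if y.all() or not y.any():
            degenerate += 1
            continue
        a, se, sp, _ = _point(scores[idx], y)
        boots.append((a, se, sp))
    if boots:
        arr = np.asarray(boots)
        cis = [tuple(np.percentile(arr[:, j], [2.5, 97.5])) for j in range(3)]
    else:
        cis = [(auc, auc), (sens, sens), (spec, spec)]
    return ClassificationReport(
        auc=auc, auc_ci=cis[0],
        sensitivity=sens, sens_ci=cis[1],
        specificity=spec, spec_ci=cis[2],
        threshold_hu=threshold_hu,
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_boot=n_boot, n_degenerate_replicates=degenerate,
    )
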