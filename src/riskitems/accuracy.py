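"""Diagnostic-accuracy statistics for binary predictors of repeat self-harm.

Dual statistics (sensitivity/specificity, predictive values, likelihood
ratios) are computed from 2x2 tables built after listwise exclusion of
episodes missing the analysed item; global accuracy is the area under the
empirical ROC curve, computed by the Mann-Whitney identity

    AUC = P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg)

which equals the trapezoidal area under the empirical ROC with the
"predicted positive iff score >= threshold" convention. For a single binary
item the AUC reduces to (sensitivity + specificity) / 2 exactly.

Interval methods (none is canonical for this kind of study, so all are
selectable): Wilson score (default), Clopper-Pearson or Wald for
proportions; Hanley-McNeil for AUC; Simel's log method for likelihood
ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateInputError

__all__ = [
    "TwoByTwo",
    "AccuracyResult",
    "AUCResult",
    "two_by_two",
    "dual_statistics",
    "proportion_ci",
    "roc_auc",
    "binary_auc",
    "PROPORTION_CI_METHODS",
]

PROPORTION_CI_METHODS = ("wilson", "clopper-pearson", "wald")
_STATSMODELS_METHOD = {"wilson": "wilson", "clopper-pearson": "beta", "wald": "normal"}


@dataclass(frozen=True)
class TwoByTwo:
    """Counts from cross-classifying a binary prediction against the outcome."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn, self.n_excluded) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @property
    def n_analysed(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class AccuracyResult:
    """Dual statistics with confidence intervals; undefined entries are NaN."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    lr_pos_ci: tuple[float, float]
    lr_neg_ci: tuple[float, float]
    n_analysed: int
    n_excluded: int
    ci_method: str = "wilson"


@dataclass(frozen=True)
class AUCResult:
    """Area under the empirical ROC curve with a confidence interval."""

    auc: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int


def _to_binary(series: pd.Series) -> pd.Series:
    """Coerce 0/1 or low/high labels to a nullable 0/1 series."""
    if series.dtype == object or pd.api.types.is_string_dtype(series):
        mapped = series.map({"low": 0, "high": 1, 0: 0, 1: 1})
        unknown = series.notna() & mapped.isna()
        if unknown.any():
            raise ValueError(f"unrecognised prediction labels: {set(series[unknown])}")
        return mapped.astype("Int64")
    return pd.Series(pd.array(series, dtype="Float64"), index=series.index).astype("Int64")


def two_by_two(predictions, outcomes) -> TwoByTwo:
    """Cross-classify predictions against outcomes with listwise exclusion.

    Episodes with a missing prediction are excluded (counted in
    ``n_excluded``); outcomes must be complete. Predictions may be 0/1 or
    'low'/'high' labels.
    """
    pred = _to_binary(pd.Series(predictions).reset_index(drop=True))
    out = pd.Series(outcomes).reset_index(drop=True)
    if len(pred) != len(out):
        raise ValueError("predictions and outcomes differ in length")
    if out.isna().any():
        raise ValueError("outcomes must never be missing")
    out = out.astype(int)
    keep = pred.notna()
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise DegenerateInputError("no episodes remain after listwise exclusion")
    p = pred[keep].astype(int)
    o = out[keep]
    return TwoByTwo(
        tp=int(((p == 1) & (o == 1)).sum()),
        fp=int(((p == 1) & (o == 0)).sum()),
        fn=int(((p == 0) & (o == 1)).sum()),
        tn=int(((p == 0) & (o == 0)).sum()),
        n_excluded=n_excluded,
    )


def proportion_ci(k: int, n: int, method: str = "wilson", alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided binomial confidence interval for k successes out of n."""
    if n <= 0:
        raise DegenerateInputError("proportion CI needs n > 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if method not in _STATSMODELS_METHOD:
        raise ValueError(f"unknown CI method {method!r}; choose from {PROPORTION_CI_METHODS}")
    lo, hi = proportion_confint(k, n, alpha=alpha, method=_STATSMODELS_METHOD[method])
    return (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))


def _lr_ci(lr: float, a: int, m: int, b: int, n: int, alpha: float) -> tuple[float, float]:
    """Simel log-method interval for a likelihood ratio a/m over b/n."""
    if not math.isfinite(lr) or lr <= 0 or a == 0 or b == 0:
        return (float("nan"), float("nan"))
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a - 1 / m + 1 / b - 1 / n)
    return (lr * math.exp(-z * se), lr * math.exp(z * se))


def dual_statistics(t: TwoByTwo, ci_method: str = "wilson", alpha: float = 0.05) -> AccuracyResult:
    """Sensitivity, specificity, predictive values and likelihood ratios with CIs.

    Requires at least one analysed episode in each outcome class. A zero
    denominator leaves the affected statistic (and its interval) as NaN
    rather than raising.
    """
    if t.n_positive == 0 or t.n_negative == 0:
        raise DegenerateInputError("dual statistics need both outcome classes")
    nan_ci = (float("nan"), float("nan"))

    def prop(k: int, n: int) -> tuple[float, tuple[float, float]]:
        if n == 0:
            return float("nan"), nan_ci
        return k / n, proportion_ci(k, n, ci_method, alpha)

    sens, sens_ci = prop(t.tp, t.n_positive)
    spec, spec_ci = prop(t.tn, t.n_negative)
    ppv, ppv_ci = prop(t.tp, t.tp + t.fp)
    npv, npv_ci = prop(t.tn, t.tn + t.fn)
    lr_pos = sens / (1 - spec) if spec < 1 else float("nan")
    lr_neg = (1 - sens) / spec if spec > 0 else float("nan")
    return AccuracyResult(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        ppv_ci=ppv_ci,
        npv_ci=npv_ci,
        lr_pos_ci=_lr_ci(lr_pos, t.tp, t.n_positive, t.fp, t.n_negative, alpha),
        lr_neg_ci=_lr_ci(lr_neg, t.fn, t.n_positive, t.tn, t.n_negative, alpha),
        n_analysed=t.n_analysed,
        n_excluded=t.n_excluded,
        ci_method=ci_method,
    )


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int, alpha: float) -> tuple[float, float]:
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc_auc(scores, outcomes, alpha: float = 0.05) -> AUCResult:
    """Area under the empirical ROC curve via the Mann-Whitney rank identity.

    Episodes with a missing score are excluded listwise; ties contribute 1/2.
    Both outcome classes must remain after exclusion. The interval is
    Hanley-McNeil, clipped to [0, 1].
    """
    s = pd.Series(pd.array(scores, dtype="Float64")).reset_index(drop=True)
    o = pd.Series(outcomes).reset_index(drop=True)
    if len(s) != len(o):
        raise ValueError("scores and outcomes differ in length")
    if o.isna().any():
        raise ValueError("outcomes must never be missing")
    keep = s.notna()
    x = s[keep].astype(float).to_numpy()
    y = o[keep].astype(int).to_numpy()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("ROC needs both outcome classes after exclusion")
    ranks = stats.rankdata(x)  # midranks give the half-tie rule
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return AUCResult(
        auc=float(auc),
        ci=_hanley_mcneil_ci(float(auc), n_pos, n_neg, alpha),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def binary_auc(t: TwoByTwo) -> float:
    """AUC of a single binary predictor: (sensitivity + specificity) / 2.

    Exactly equals :func:`roc_auc` applied to the expanded 0/1 score vector.
    """
    if t.n_positive == 0 or t.n_negative == 0:
        raise DegenerateInputError("binary AUC needs both outcome classes")
    sens = t.tp / t.n_positive
    spec = t.tn / t.n_negative
    return (sens + spec) / 2.0
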