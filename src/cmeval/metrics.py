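"""Confusion-matrix rates and multi-category metrics.

The four basic rates condition on one margin each:

    TPR = TP/(TP+FN)    sensitivity / recall
    TNR = TN/(TN+FP)    specificity
    PPV = TP/(TP+FP)    precision
    NPV = TN/(TN+FN)

with complements FNR, FPR, FDR, FOR.  A rate whose denominator is zero is
UNDEFINED (no limit exists; see :mod:`cmeval.types`).

Multi-category metrics:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    BA  = (TPR + TNR) / 2
    BM  = TPR + TNR - 1      (bookmaker informedness, Youden's J)
    MK  = PPV + NPV - 1      (markedness)
    accuracy = (TP + TN) / N
    F1  = 2 * PPV * TPR / (PPV + TPR)

MCC is the Pearson correlation between the reference and predicted label
vectors and is extended to a total function: when any marginal sum is
zero the value 0 is returned (the conventional always-defined extension)
and the panel carries a degeneracy flag.  BA/BM are UNDEFINED exactly
when (TP+FN)(TN+FP) = 0, MK exactly when (TP+FP)(TN+FN) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix import ConfusionMatrix
from .types import UNDEFINED, MetricValue, format_value, is_defined

__all__ = [
    "BasicRates",
    "MetricPanel",
    "basic_rates",
    "mcc",
    "balanced_accuracy",
    "bookmaker",
    "markedness",
    "accuracy",
    "f1",
    "metric_panel",
    "mcc_array",
    "bm_array",
    "mk_array",
    "ba_array",
]


def _ratio(num: int, den: int) -> MetricValue:
    return UNDEFINED if den == 0 else num / den


@dataclass(frozen=True, slots=True)
class BasicRates:
    """The eight one-margin rates of a confusion matrix."""

    tpr: MetricValue
    tnr: MetricValue
    ppv: MetricValue
    npv: MetricValue
    fdr: MetricValue
    fnr: MetricValue
    fpr: MetricValue
    for_: MetricValue


def basic_rates(cm: ConfusionMatrix) -> BasicRates:
    """Compute TPR, TNR, PPV, NPV and their complements.

    Each complement (FDR = 1-PPV, FNR = 1-TPR, FPR = 1-TNR, FOR = 1-NPV)
    is UNDEFINED exactly when its base rate is.
    """
    tpr = _ratio(cm.tp, cm.tp + cm.fn)
    tnr = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    return BasicRates(
        tpr=tpr, tnr=tnr, ppv=ppv, npv=npv,
        fdr=1 - ppv, fnr=1 - tpr, fpr=1 - tnr, for_=1 - npv,
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient, total over all matrices.

    Computed exactly in integer arithmetic before the final square root.
    When any of the four marginal sums is zero the correlation is
    formally 0/0; the conventional extension value 0.0 is returned so the
    metric is defined for every matrix (see :func:`metric_panel` for the
    degeneracy flag).
    """
    s_pred_pos = cm.tp + cm.fp
    s_actual_pos = cm.tp + cm.fn
    s_pred_neg = cm.tn + cm.fn
    s_actual_neg = cm.tn + cm.fp
    denom_sq = s_pred_pos * s_actual_pos * s_actual_neg * s_pred_neg
    if denom_sq == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom_sq)


def mcc_is_degenerate(cm: ConfusionMatrix) -> bool:
    """True when the MCC denominator vanishes (a whole row or column is 0)."""
    return min(cm.tp + cm.fp, cm.tp + cm.fn, cm.tn + cm.fp, cm.tn + cm.fn) == 0


def balanced_accuracy(cm: ConfusionMatrix) -> MetricValue:
    """BA = (TPR + TNR)/2; UNDEFINED when (TP+FN)(TN+FP) = 0."""
    r = basic_rates(cm)
    return (r.tpr + r.tnr) / 2


def bookmaker(cm: ConfusionMatrix) -> MetricValue:
    """Bookmaker informedness BM = TPR + TNR - 1 (Youden's J).

    UNDEFINED when a reference class is absent, i.e. (TP+FN)(TN+FP) = 0.
    """
    r = basic_rates(cm)
    return r.tpr + r.tnr - 1


def markedness(cm: ConfusionMatrix) -> MetricValue:
    """Markedness MK = PPV + NPV - 1; UNDEFINED when (TP+FP)(TN+FN) = 0."""
    r = basic_rates(cm)
    return r.ppv + r.npv - 1


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN)/N; equals TPR*phi + TNR*(1-phi) whenever both rates exist."""
    return (cm.tp + cm.tn) / cm.n


def f1(cm: ConfusionMatrix) -> MetricValue:
    """F1 = harmonic mean of precision and recall.

    UNDEFINED when PPV or TPR is UNDEFINED, or when both are zero.
    """
    r = basic_rates(cm)
    if not (is_defined(r.ppv) and is_defined(r.tpr)):
        return UNDEFINED
    if r.ppv + r.tpr == 0:
        return UNDEFINED
    return 2 * r.ppv * r.tpr / (r.ppv + r.tpr)


@dataclass(frozen=True, slots=True)
class MetricPanel:
    """All rates and multi-category metrics of one confusion matrix.

    ``mcc_degenerate`` flags matrices where the MCC denominator vanishes
    and the total extension value 0 was substituted (this includes the
    perfect-degenerate matrices tp = N or tn = N).
    """

    tpr: MetricValue
    tnr: MetricValue
    ppv: MetricValue
    npv: MetricValue
    fdr: MetricValue
    fnr: MetricValue
    fpr: MetricValue
    for_: MetricValue
    mcc: float
    ba: MetricValue
    bm: MetricValue
    mk: MetricValue
    accuracy: float
    f1: MetricValue
    mcc_degenerate: bool = False

    _METRIC_FIELDS = (
        "tpr", "tnr", "ppv", "npv", "fdr", "fnr", "fpr", "for_",
        "mcc", "ba", "bm", "mk", "accuracy", "f1",
    )

    def as_dict(self) -> dict[str, MetricValue]:
        return {name: getattr(self, name) for name in self._METRIC_FIELDS}

    def formatted(self, precision: int | None = 3) -> dict[str, str]:
        return {k: format_value(v, precision) for k, v in self.as_dict().items()}

    def __getitem__(self, name: str) -> MetricValue:
        key = "for_" if name == "for" else name
        if key not in self._METRIC_FIELDS:
            raise KeyError(name)
        return getattr(self, key)


def metric_panel(cm: ConfusionMatrix) -> MetricPanel:
    """Compute every metric of *cm* consistently in one pass."""
    r = basic_rates(cm)
    return MetricPanel(
        tpr=r.tpr, tnr=r.tnr, ppv=r.ppv, npv=r.npv,
        fdr=r.fdr, fnr=r.fnr, fpr=r.fpr, for_=r.for_,
        mcc=mcc(cm),
        ba=(r.tpr + r.tnr) / 2,
        bm=r.tpr + r.tnr - 1,
        mk=r.ppv + r.npv - 1,
        accuracy=accuracy(cm),
        f1=f1(cm),
        mcc_degenerate=mcc_is_degenerate(cm),
    )


# ---------------------------------------------------------------------------
# Vectorized forms over count arrays.  UNDEFINED maps to NaN; MCC keeps its
# total (zero-extended) definition so it never produces NaN.  Counts are
# promoted to float64 before forming marginal products to avoid overflow.
# ---------------------------------------------------------------------------

def _as_float(*arrays):
    return tuple(np.asarray(a, dtype=np.float64) for a in arrays)


def mcc_array(tp, fn, fp, tn) -> np.ndarray:
    tp, fn, fp, tn = _as_float(tp, fn, fp, tn)
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    num = tp * tn - fp * fn
    out = np.zeros(np.broadcast(tp, fn, fp, tn).shape)
    ok = denom_sq > 0
    out[ok] = num[ok] / np.sqrt(denom_sq[ok])
    return out


def _rate_array(num, den) -> np.ndarray:
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def bm_array(tp, fn, fp, tn) -> np.ndarray:
    tp, fn, fp, tn = _as_float(tp, fn, fp, tn)
    return _rate_array(tp, tp + fn) + _rate_array(tn, tn + fp) - 1.0


def ba_array(tp, fn, fp, tn) -> np.ndarray:
    return (bm_array(tp, fn, fp, tn) + 1.0) / 2.0


def mk_array(tp, fn, fp, tn) -> np.ndarray:
    tp, fn, fp, tn = _as_float(tp, fn, fp, tn)
    return _rate_array(tp, tp + fp) + _rate_array(tn, tn + fn) - 1.0
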