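"""Prevalence/bias reparameterization of the confusion matrix.

A confusion matrix of size N is determined losslessly by the coordinates
(N, phi, TPR, TNR):

    phi = (TP + FN)/N                  prevalence (dataset intrinsic)
    beta = (TP + FP)/N                 bias = TPR*phi + (1-TNR)*(1-phi)

    TP = N * TPR * phi                 FN = N * (1-TPR) * phi
    TN = N * TNR * (1-phi)             FP = N * (1-TNR) * (1-phi)

TPR and TNR describe the classifier alone; phi (and hence beta, PPV, NPV,
MCC, MK) mixes in the dataset.  The predictive values follow from the
rates by Bayes' rule and vice versa:

    PPV = TPR*phi / (TPR*phi + (1-TNR)*(1-phi))
    NPV = TNR*(1-phi) / ((1-TPR)*phi + TNR*(1-phi))
    TPR = PPV*beta / (PPV*beta + (1-NPV)*(1-beta))
    TNR = NPV*(1-beta) / ((1-PPV)*beta + NPV*(1-beta))

When phi is 0 or 1 one reference class is absent and the corresponding
rate is non-identifiable from counts; :func:`rates_from_cm` records NaN
for it and :func:`cm_from_rates` ignores it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .matrix import ConfusionMatrix, RelativeConfusionMatrix
from .types import UNDEFINED, MetricValue

__all__ = [
    "RateParameterization",
    "prevalence",
    "bias",
    "rates_from_cm",
    "cm_from_rates",
    "counts_from_rates",
    "ppv_from_rates",
    "npv_from_rates",
    "tpr_from_predictive",
    "tnr_from_predictive",
]


def _check_unit(value: float, name: str, allow_nan: bool = False) -> float:
    value = float(value)
    if math.isnan(value):
        if allow_nan:
            return value
        raise ValueError(f"{name} must not be NaN")
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True, slots=True)
class RateParameterization:
    """(N, phi, TPR, TNR): the lossless alternative coordinates.

    A NaN rate marks the non-identifiable case where the class it
    describes is absent (phi exactly 0 or 1); such a rate carries no
    information and round-trips are not expected to preserve it.
    """

    n: int
    phi: float
    tpr: float
    tnr: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "phi", _check_unit(self.phi, "phi"))
        object.__setattr__(self, "tpr", _check_unit(self.tpr, "tpr", allow_nan=True))
        object.__setattr__(self, "tnr", _check_unit(self.tnr, "tnr", allow_nan=True))


def prevalence(cm: ConfusionMatrix) -> float:
    """phi = (TP + FN)/N, the share of reference positives."""
    return (cm.tp + cm.fn) / cm.n


def bias(cm: ConfusionMatrix) -> float:
    """beta = (TP + FP)/N, the share of positive predictions."""
    return (cm.tp + cm.fp) / cm.n


def rates_from_cm(cm: ConfusionMatrix) -> RateParameterization:
    """Invert the count matrix into (N, phi, TPR, TNR) coordinates.

    The rate of an absent reference class is recorded as NaN
    (non-identifiable), never silently as 0 or 1.
    """
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    return RateParameterization(
        n=cm.n,
        phi=pos / cm.n,
        tpr=cm.tp / pos if pos else math.nan,
        tnr=cm.tn / neg if neg else math.nan,
    )


def cm_from_rates(p: RateParameterization) -> RelativeConfusionMatrix:
    """Shares (TP, FN, FP, TN)/N from the rate coordinates.

    tp = TPR*phi, fn = (1-TPR)*phi, fp = (1-TNR)*(1-phi), tn = TNR*(1-phi);
    the four shares sum to 1 by construction.  When phi is 0 (or 1) the
    positive (negative) row is zero regardless of its rate.
    """
    if p.phi > 0:
        if math.isnan(p.tpr):
            raise ValueError("tpr is required when phi > 0")
        tp, fn = p.tpr * p.phi, (1.0 - p.tpr) * p.phi
    else:
        tp = fn = 0.0
    if p.phi < 1:
        if math.isnan(p.tnr):
            raise ValueError("tnr is required when phi < 1")
        tn, fp = p.tnr * (1.0 - p.phi), (1.0 - p.tnr) * (1.0 - p.phi)
    else:
        tn = fp = 0.0
    return RelativeConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def counts_from_rates(p: RateParameterization) -> ConfusionMatrix:
    """Count matrix for sample size ``p.n``, largest-remainder rounded.

    Emits :class:`cmeval.matrix.CountRoundingWarning` when the shares
    times N are far from integers (an entry moved by >= 0.5).
    """
    return cm_from_rates(p).to_counts(p.n)


def ppv_from_rates(tpr: float, tnr: float, phi: float) -> MetricValue:
    """PPV by Bayes' rule from sensitivity, specificity and prevalence."""
    tpr = _check_unit(tpr, "tpr")
    tnr = _check_unit(tnr, "tnr")
    phi = _check_unit(phi, "phi")
    den = tpr * phi + (1.0 - tnr) * (1.0 - phi)
    return UNDEFINED if den == 0 else tpr * phi / den


def npv_from_rates(tpr: float, tnr: float, phi: float) -> MetricValue:
    """NPV by Bayes' rule from sensitivity, specificity and prevalence."""
    tpr = _check_unit(tpr, "tpr")
    tnr = _check_unit(tnr, "tnr")
    phi = _check_unit(phi, "phi")
    den = (1.0 - tpr) * phi + tnr * (1.0 - phi)
    return UNDEFINED if den == 0 else tnr * (1.0 - phi) / den


def tpr_from_predictive(ppv: float, npv: float, beta: float) -> MetricValue:
    """Recover TPR from the predictive values and the prediction bias."""
    ppv = _check_unit(ppv, "ppv")
    npv = _check_unit(npv, "npv")
    beta = _check_unit(beta, "beta")
    den = ppv * beta + (1.0 - npv) * (1.0 - beta)
    return UNDEFINED if den == 0 else ppv * beta / den


def tnr_from_predictive(ppv: float, npv: float, beta: float) -> MetricValue:
    """Recover TNR from the predictive values and the prediction bias."""
    ppv = _check_unit(ppv, "ppv")
    npv = _check_unit(npv, "npv")
    beta = _check_unit(beta, "beta")
    den = (1.0 - ppv) * beta + npv * (1.0 - beta)
    return UNDEFINED if den == 0 else npv * (1.0 - beta) / den
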