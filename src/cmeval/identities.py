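"""Derived relationships between the multi-category metrics.

Writing every metric in (phi, beta, TPR, TNR) coordinates yields a small
algebra connecting them:

    BA  = (BM + 1)/2
    MCC = sqrt(PPV*TPR*TNR*NPV) - sqrt(FDR*FNR*FPR*FOR)
    MCC = sqrt((phi - phi^2)/(beta - beta^2)) * BM
    MCC = sqrt((beta - beta^2)/(phi - phi^2)) * MK
    MK  = ((phi - phi^2)/(beta - beta^2)) * BM
    MCC = sign(BM) * sqrt(BM * MK)       (geometric-mean form)

The two prefactors are reciprocals, so MCC always shares the sign of BM
and of MK, and lies between them in magnitude: if the class imbalance
|0.5 - phi| exceeds the prediction imbalance |0.5 - beta| then
|MCC| < |BM| and |MCC| > |MK|, and vice versa.  The randomness index
1 - |BM| measures how close a classifier's behavior is to random
guessing (0 for a perfect or perfectly inverted classifier, 1 for
coin-flipping), a question neither MCC nor MK answers without distortion
from phi and beta.

:func:`check_all_identities` evaluates every identity numerically
against direct computation from counts and reports the absolute errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .matrix import ConfusionMatrix
from .metrics import MetricPanel, metric_panel, mcc as mcc_direct
from .reparam import bias, prevalence
from .types import UNDEFINED, MetricValue, is_defined

__all__ = [
    "IdentityReport",
    "SignInconsistencyError",
    "ba_from_bm",
    "mcc_product_form",
    "mcc_from_bm",
    "mcc_from_mk",
    "mk_from_bm",
    "mcc_geometric_mean",
    "randomness_index",
    "check_all_identities",
    "IDENTITY_TOLERANCE",
]

#: Absolute tolerance for the numeric identity checks.  All quantities are
#: smooth rational/radical functions of the counts with magnitude <= 1, so
#: double precision comfortably supports 1e-10.
IDENTITY_TOLERANCE = 1e-10


class SignInconsistencyError(ValueError):
    """Raised when BM and MK of allegedly one matrix have opposite signs."""


def ba_from_bm(bm: MetricValue) -> MetricValue:
    """BA = (BM + 1)/2; the affine map making BA and BM interchangeable."""
    if not is_defined(bm):
        return UNDEFINED
    return (bm + 1.0) / 2.0


def mcc_product_form(panel: MetricPanel) -> MetricValue:
    """MCC as sqrt(PPV*TPR*TNR*NPV) - sqrt(FDR*FNR*FPR*FOR).

    Requires all eight rates defined; UNDEFINED otherwise.  High MCC
    therefore forces all four basic rates to be high simultaneously.
    """
    rates = (panel.ppv, panel.tpr, panel.tnr, panel.npv,
             panel.fdr, panel.fnr, panel.fpr, panel.for_)
    if not all(is_defined(r) for r in rates):
        return UNDEFINED
    pos = panel.ppv * panel.tpr * panel.tnr * panel.npv
    neg = panel.fdr * panel.fnr * panel.fpr * panel.for_
    return math.sqrt(pos) - math.sqrt(neg)


def _prefactor(phi: float, beta: float) -> float | None:
    num = phi - phi * phi
    den = beta - beta * beta
    if num <= 0 or den <= 0:
        return None
    return math.sqrt(num / den)


def mcc_from_bm(bm: MetricValue, phi: float, beta: float) -> MetricValue:
    """MCC = sqrt((phi - phi^2)/(beta - beta^2)) * BM.

    UNDEFINED on the boundary (phi or beta in {0, 1}) or when BM is.
    The prefactor is positive, so the result always shares BM's sign.
    """
    if not is_defined(bm):
        return UNDEFINED
    factor = _prefactor(phi, beta)
    return UNDEFINED if factor is None else factor * bm


def mcc_from_mk(mk: MetricValue, phi: float, beta: float) -> MetricValue:
    """MCC = sqrt((beta - beta^2)/(phi - phi^2)) * MK (reciprocal prefactor)."""
    if not is_defined(mk):
        return UNDEFINED
    factor = _prefactor(beta, phi)
    return UNDEFINED if factor is None else factor * mk


def mk_from_bm(bm: MetricValue, phi: float, beta: float) -> MetricValue:
    """MK = ((phi - phi^2)/(beta - beta^2)) * BM: markedness from informedness."""
    if not is_defined(bm):
        return UNDEFINED
    factor = _prefactor(phi, beta)
    return UNDEFINED if factor is None else factor * factor * bm


def mcc_geometric_mean(bm: MetricValue, mk: MetricValue) -> MetricValue:
    """MCC = +/- sqrt(BM * MK), signed like BM (equivalently MK).

    BM and MK originating from one matrix always agree in sign, which
    resolves the sign ambiguity of the square root; inputs of strictly
    opposite sign cannot come from one matrix and raise
    :class:`SignInconsistencyError`.
    """
    if not (is_defined(bm) and is_defined(mk)):
        return UNDEFINED
    if bm * mk < 0:
        raise SignInconsistencyError(
            f"BM ({bm}) and MK ({mk}) have opposite signs; "
            "they cannot originate from a single confusion matrix"
        )
    return math.copysign(math.sqrt(bm * mk), bm if bm != 0 else mk)


def randomness_index(bm: MetricValue) -> MetricValue:
    """1 - |BM|: how close the classifier is to random guessing.

    0 for a fully informed (or fully inverted, deceptive) classifier, 1
    for pure guessing.  Taking |BM| keeps the index in [0, 1]: a
    deceptive classifier (BM < 0) is just as far from randomness as its
    label-flipped counterpart.
    """
    if not is_defined(bm):
        return UNDEFINED
    return 1.0 - abs(bm)


@dataclass(frozen=True, slots=True)
class IdentityReport:
    """Numeric check of one identity: |lhs - rhs| against a tolerance.

    ``applicable`` is False when the identity's ingredients are
    UNDEFINED for the matrix at hand (degenerate margins); then lhs, rhs
    and abs_error are NaN and ``holds`` is False.
    """

    name: str
    lhs: float
    rhs: float
    abs_error: float
    holds: bool
    applicable: bool
    tolerance: float = IDENTITY_TOLERANCE


def _report(name: str, lhs: MetricValue, rhs: MetricValue,
            tolerance: float) -> IdentityReport:
    if not (is_defined(lhs) and is_defined(rhs)):
        return IdentityReport(name, math.nan, math.nan, math.nan,
                              holds=False, applicable=False, tolerance=tolerance)
    err = abs(lhs - rhs)
    return IdentityReport(name, float(lhs), float(rhs), err,
                          holds=err <= tolerance, applicable=True,
                          tolerance=tolerance)


def check_all_identities(cm: ConfusionMatrix,
                         tolerance: float = IDENTITY_TOLERANCE) -> list[IdentityReport]:
    """Evaluate every inter-metric identity on *cm* against direct values.

    Identities whose ingredients are undefined for a degenerate matrix
    are reported as not applicable rather than failing.
    """
    panel = metric_panel(cm)
    phi = prevalence(cm)
    beta = bias(cm)
    direct = mcc_direct(cm)

    bias_rate_form = (
        panel.tpr * phi + (1.0 - panel.tnr) * (1.0 - phi)
        if is_defined(panel.tpr) and is_defined(panel.tnr)
        else UNDEFINED
    )

    geo = UNDEFINED
    if is_defined(panel.bm) and is_defined(panel.mk):
        geo = mcc_geometric_mean(panel.bm, panel.mk)

    checks = [
        ("ba_from_bm", panel.ba, ba_from_bm(panel.bm)),
        ("mcc_product_form", direct, mcc_product_form(panel)),
        ("mcc_from_bm", direct, mcc_from_bm(panel.bm, phi, beta)),
        ("mcc_from_mk", direct, mcc_from_mk(panel.mk, phi, beta)),
        ("mk_from_bm", panel.mk, mk_from_bm(panel.bm, phi, beta)),
        ("mcc_geometric_mean", direct, geo),
        ("bias_two_forms", beta, bias_rate_form),
    ]
    return [_report(name, lhs, rhs, tolerance) for name, lhs, rhs in checks]
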