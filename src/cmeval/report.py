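"""Formatted text reports for the bundled worked examples."""

from __future__ import annotations

import math

from .fixtures import NamedClassifierResult, load_fixture
from .identities import check_all_identities
from .matrix import ConfusionMatrix, swap_labels
from .metrics import metric_panel
from .ranking import rank_classifiers
from .reparam import bias, npv_from_rates, ppv_from_rates, prevalence, rates_from_cm
from .types import format_value, is_defined

__all__ = ["use_case_report", "panel_report"]


def _fmt(value, precision: int) -> str:
    return format_value(value, precision)


def panel_report(name: str, cm: ConfusionMatrix, precision: int = 3) -> str:
    """Matrix, coordinates and full metric panel as aligned text."""
    panel = metric_panel(cm)
    lines = [
        f"{name}: {cm}  (N={cm.n})",
        f"  prevalence phi={_fmt(prevalence(cm), precision)}  "
        f"bias beta={_fmt(bias(cm), precision)}",
        "  rates:   " + "  ".join(
            f"{key.rstrip('_').upper()}={_fmt(panel[key], precision)}"
            for key in ("tpr", "tnr", "ppv", "npv")
        ),
        "  metrics: " + "  ".join(
            f"{key.upper()}={_fmt(panel[key], precision)}"
            for key in ("mcc", "ba", "bm", "mk", "accuracy", "f1")
        ),
    ]
    if panel.mcc_degenerate:
        lines.append("  note: MCC denominator is zero; total-extension value 0 reported")
    return "\n".join(lines)


def _identity_block(cm: ConfusionMatrix, precision: int) -> list[str]:
    lines = ["  identity checks:"]
    for rep in check_all_identities(cm):
        if not rep.applicable:
            status = "not applicable (degenerate margins)"
        else:
            status = ("holds" if rep.holds else "FAILS") + \
                f"  lhs={rep.lhs:.{precision}f} rhs={rep.rhs:.{precision}f} |err|={rep.abs_error:.1e}"
        lines.append(f"    {rep.name:<20s} {status}")
    return lines


def _uc1_block(cm: ConfusionMatrix, precision: int) -> list[str]:
    p = rates_from_cm(cm)
    ppv = ppv_from_rates(p.tpr, p.tnr, p.phi)
    npv = npv_from_rates(p.tpr, p.tnr, p.phi)
    lines = [
        "  pre/post-test probability of a positive instance:",
        f"    before testing      phi     = {_fmt(p.phi, precision)}",
        f"    testing positive    PPV     = {_fmt(ppv, precision)}",
        f"    testing negative    1 - NPV = {_fmt(1 - npv, 5)}",
    ]
    if is_defined(ppv) and p.phi > 0:
        lines.append(
            f"    a positive result multiplies the probability by "
            f"{ppv / p.phi:.1f}"
        )
    return lines


def _uc2_block(cm: ConfusionMatrix, precision: int) -> list[str]:
    panel = metric_panel(cm)
    swapped = swap_labels(cm)
    lines = []
    if is_defined(panel.ba) and abs(panel.ba - 0.5) > 0.25 and abs(panel.mcc) < 0.25:
        lines.append(
            "  warning: BA/BM suggest near-perfect prediction while MCC/MK "
            "are close to zero - the negative predictions are unreliable"
        )
    lines.append(
        f"  label swap: MCC unchanged at {_fmt(metric_panel(swapped).mcc, precision)} "
        f"(matrix becomes {swapped})"
    )
    return lines


def _uc3_block(cm: ConfusionMatrix, precision: int) -> list[str]:
    panel = metric_panel(cm)
    lines = []
    if is_defined(panel.bm) and panel.bm >= 0:
        lines.append(
            f"  MK is close to 1, so MCC ~ sqrt(BM): "
            f"sqrt({_fmt(panel.bm, precision)}) = {math.sqrt(panel.bm):.{precision}f} "
            f"vs MCC = {_fmt(panel.mcc, precision)}"
        )
    return lines


def _uc4_report(results: list[NamedClassifierResult], precision: int) -> str:
    lines = []
    for result in results:
        lines.append(panel_report(result.name, result.cm, precision))
    for metric in ("mcc", "bm"):
        ranking = rank_classifiers(results, metric)
        order = " > ".join(
            f"{e.name} ({_fmt(e.value, precision)})" for e in ranking.entries
        )
        lines.append(f"ranking by {metric.upper()}: {order}")
    tops = {m: rank_classifiers(results, m).top.name for m in ("mcc", "bm")}
    if tops["mcc"] != tops["bm"]:
        lines.append(
            f"note: MCC prefers {tops['mcc']} while BM prefers {tops['bm']} - "
            "MCC is not comparable across datasets of different prevalence"
        )
    return "\n".join(lines)


def use_case_report(name: str, precision: int = 3) -> str:
    """Render a worked example: matrix, panel, identities, commentary."""
    fixture = load_fixture(name)
    if isinstance(fixture, list):
        return _uc4_report(fixture, precision)

    lines = [panel_report(fixture.name, fixture.cm, precision)]
    lines += _identity_block(fixture.cm, precision)
    extra = {
        "CM1": _uc1_block,
        "CM2": _uc2_block,
        "CM3": _uc3_block,
    }[fixture.name]
    lines += extra(fixture.cm, precision)
    return "\n".join(lines)
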