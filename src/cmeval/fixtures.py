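"""Bundled worked-example confusion matrices.

Three single-classifier scenarios and one two-classifier comparison:

* ``CM1`` — high sensitivity and specificity (0.99 / 0.95) on a very
  imbalanced dataset (prevalence ~0.001): BM ~ 0.94 but MCC ~ 0.136,
  because precision collapses at low prevalence.
* ``CM2`` — the label-swapped sibling: BA = 0.9 and BM = 0.8 look
  excellent while MCC ~ 0.027 and MK ~ 0.001 expose worthless negative
  predictions.
* ``CM3`` — nearly always predicting positive: BM = 0.091 (barely
  informed) yet MK ~ 1 and MCC ~ sqrt(BM) ~ 0.301.
* ``UC4_separate`` / ``UC4_crossed`` — classifiers A and B evaluated on
  datasets of different prevalence; ranking by MCC and by BM invert.

Each fixture also records the published truncated relative shares for
cross-checking against the exact count-derived shares.
"""

from __future__ import annotations

from dataclasses import dataclass

from .matrix import ConfusionMatrix
from .metrics import MetricPanel, metric_panel

__all__ = ["NamedClassifierResult", "load_fixture", "printed_relative", "FIXTURE_NAMES"]


@dataclass(frozen=True, slots=True)
class NamedClassifierResult:
    """A labelled confusion matrix with its computed metric panel."""

    name: str
    cm: ConfusionMatrix
    panel: MetricPanel

    @classmethod
    def from_cm(cls, name: str, cm: ConfusionMatrix) -> "NamedClassifierResult":
        return cls(name=name, cm=cm, panel=metric_panel(cm))


_SINGLE = {
    "CM1": ConfusionMatrix(tp=100, fn=1, fp=5000, tn=94900),
    "CM2": ConfusionMatrix(tp=90000, fn=10000, fp=1, tn=9),
    "CM3": ConfusionMatrix(tp=90000, fn=0, fp=10, tn=1),
}

# Published relative shares (truncated to ~3 significant figures; they do
# not sum to exactly 1, so they are comparison data, not constructors).
_PRINTED_RELATIVE = {
    "CM1": (9.99e-4, 9.99e-6, 0.05, 0.95),
    "CM2": (8.99e-1, 9.99e-2, 9.99e-6, 8.99e-5),
    "CM3": (0.999877792, 0.0, 1.11e-4, 1.11e-5),
}

# Classifiers A and B; dataset 1 is balanced (phi=0.5), dataset 2
# imbalanced (phi=0.05); both at sample size 200.
_UC4_MATRICES = {
    "A@1": ConfusionMatrix(tp=70, fn=30, fp=30, tn=70),
    "A@2": ConfusionMatrix(tp=7, fn=3, fp=57, tn=133),
    "B@1": ConfusionMatrix(tp=80, fn=20, fp=20, tn=80),
    "B@2": ConfusionMatrix(tp=8, fn=2, fp=38, tn=152),
}

# A published on dataset 1, B published on dataset 2 (separate sources).
_UC4_SEPARATE = ("A@1", "B@2")
# Both classifiers evaluated on both datasets.
_UC4_CROSSED = ("A@1", "A@2", "B@1", "B@2")

FIXTURE_NAMES = ("CM1", "CM2", "CM3", "UC4_separate", "UC4_crossed")


def load_fixture(name: str):
    """Return the named worked example.

    ``CM1``/``CM2``/``CM3`` return one :class:`NamedClassifierResult`;
    ``UC4_separate``/``UC4_crossed`` return a list of them.
    """
    key = name.strip()
    lowered = key.lower()
    for candidate in FIXTURE_NAMES:
        if candidate.lower() == lowered:
            key = candidate
            break
    else:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    if key in _SINGLE:
        return NamedClassifierResult.from_cm(key, _SINGLE[key])
    members = _UC4_SEPARATE if key == "UC4_separate" else _UC4_CROSSED
    return [NamedClassifierResult.from_cm(m, _UC4_MATRICES[m]) for m in members]


def printed_relative(name: str) -> tuple[float, float, float, float]:
    """The published truncated relative shares (tp, fn, fp, tn) of CM1-3."""
    return _PRINTED_RELATIVE[name]
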