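"""Confusion-matrix containers and label-vector construction.

A two-class confusion matrix holds the four outcome counts of a binary
classification: true positives (TP), false negatives (FN), false
positives (FP) and true negatives (TN).  The relative form holds the four
shares (summing to 1), which removes the sample size N and is convenient
for comparing metrics across datasets, though counts should always be
reported for real evaluations since N governs the reliability of every
derived metric.
"""

from __future__ import annotations


import operator
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "RelativeConfusionMatrix",
    "CountRoundingWarning",
    "swap_labels",
    "cm_from_labels",
]


class CountRoundingWarning(UserWarning):
    """Emitted when converting shares to counts moved an entry by >= 0.5."""


def _as_count(value, field: str) -> int:
    try:
        count = operator.index(value)
    except TypeError:
        if isinstance(value, float) and value.is_integer():
            count = int(value)
        else:
            raise TypeError(f"{field} must be an integer count, got {value!r}") from None
    if count < 0:
        raise ValueError(f"{field} must be non-negative, got {count}")
    return count


@dataclass(frozen=True, slots=True)
class ConfusionMatrix:
    """Counts of a binary classification outcome.

    Laid out as ``[[tp, fn], [fp, tn]]``: rows are the reference
    (actual) class, columns the predicted class.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for field in ("tp", "fn", "fp", "tn"):
            object.__setattr__(self, field, _as_count(getattr(self, field), field))
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def n(self) -> int:
        """Total sample size N = TP + FN + FP + TN."""
        return self.tp + self.fn + self.fp + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fn, self.fp, self.tn)

    def relative(self) -> "RelativeConfusionMatrix":
        """The share form: each count divided by N."""
        n = self.n
        return RelativeConfusionMatrix(self.tp / n, self.fn / n, self.fp / n, self.tn / n)

    def __iter__(self) -> Iterator[int]:
        return iter(self.as_tuple())

    def __str__(self) -> str:
        return f"[[TP={self.tp} FN={self.fn}] [FP={self.fp} TN={self.tn}]]"


@dataclass(frozen=True, slots=True)
class RelativeConfusionMatrix:
    """Shares of the four outcomes; must sum to 1 within 1e-9."""

    tp: float
    fn: float
    fp: float
    tn: float

    _SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        for field in ("tp", "fn", "fp", "tn"):
            value = float(getattr(self, field))
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{field} share must lie in [0, 1], got {value}")
            object.__setattr__(self, field, value)
        total = self.tp + self.fn + self.fp + self.tn
        if abs(total - 1.0) > self._SUM_TOL:
            raise ValueError(f"shares must sum to 1 (got {total!r})")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.tp, self.fn, self.fp, self.tn)

    def to_counts(self, n: int) -> ConfusionMatrix:
        """Integer counts for sample size *n* by largest-remainder rounding.

        The four rounded counts always sum to exactly *n*.  When any entry
        has to move by at least 0.5 from its exact value a
        :class:`CountRoundingWarning` is emitted, since the count matrix
        then only approximates the shares.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        exact = np.array(self.as_tuple()) * n
        counts = np.floor(exact).astype(np.int64)
        leftover = int(round(n - counts.sum()))
        if leftover:
            order = np.argsort(-(exact - counts), kind="stable")
            counts[order[:leftover]] += 1
        if np.max(np.abs(counts - exact)) >= 0.5:
            warnings.warn(
                f"rounding shares to counts at n={n} moved an entry by >= 0.5",
                CountRoundingWarning,
                stacklevel=2,
            )
        return ConfusionMatrix(*counts.tolist())

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_tuple())


def swap_labels(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Exchange the roles of the positive and negative class.

    TP<->TN and FN<->FP.  MCC, BA, BM and MK are invariant under this
    relabelling (where defined); F1 in general is not.  Applying the swap
    twice returns the original matrix.
    """
    return ConfusionMatrix(tp=cm.tn, fn=cm.fp, fp=cm.fn, tn=cm.tp)


def cm_from_labels(reference: Sequence, predicted: Sequence) -> ConfusionMatrix:
    """Tally a confusion matrix from paired binary label vectors.

    Labels are interpreted as booleans (1/True = positive).  Entries must
    be binary; vectors must have equal length >= 1.
    """
    ref = np.asarray(reference)
    pred = np.asarray(predicted)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("reference and predicted must be 1-D of equal length")
    if ref.size < 1:
        raise ValueError("label vectors must contain at least one element")
    for name, arr in (("reference", ref), ("predicted", pred)):
        if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be binary (0/1 or bool)")
    ref = ref.astype(bool)
    pred = pred.astype(bool)
    tp = int(np.count_nonzero(ref & pred))
    fn = int(np.count_nonzero(ref & ~pred))
    fp = int(np.count_nonzero(~ref & pred))
    tn = int(np.count_nonzero(~ref & ~pred))
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def labels_from_cm(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct one pair of label vectors that tallies to *cm*.

    Inverse of :func:`cm_from_labels` up to ordering; useful for checking
    that MCC equals the Pearson correlation of the two label vectors.
    """
    ref = np.concatenate(
        [
            np.ones(cm.tp + cm.fn, dtype=bool),
            np.zeros(cm.fp + cm.tn, dtype=bool),
        ]
    )
    pred = np.concatenate(
        [
            np.ones(cm.tp, dtype=bool),
            np.zeros(cm.fn, dtype=bool),
            np.ones(cm.fp, dtype=bool),
            np.zeros(cm.tn, dtype=bool),
        ]
    )
    return ref, pred
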