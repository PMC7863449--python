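"""Exhaustive and random exploration of the confusion-matrix space.

For a sample size N there are C(N+3, 3) confusion matrices (weak
compositions of N into four parts).  Enumerating them all and computing
MCC, BM and MK per matrix quantifies how linearly related the metrics
are, via the Pearson correlation coefficient (PCC) between each pair
over the whole space.  The PCC curve as a function of N dips to a
minimum around N ~ 25 and then climbs back towards 1.

A matrix with an empty reference class (BM undefined) or an empty
prediction class (MK undefined) is excluded from any pair involving that
metric (pairwise deletion); MCC uses its total zero-extended definition
and never excludes.  The per-N record reports how many matrices carried
any undefined metric so the effect of the policy is visible.

Because BM and MK are images of each other under transposing the matrix
(swapping the roles of reference and prediction, fn <-> fp) while MCC is
invariant, PCC(MCC, BM) equals PCC(MCC, MK) exactly for every N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .matrix import ConfusionMatrix
from .metrics import bm_array, mcc_array, mk_array
from .types import UNDEFINED, MetricValue

__all__ = [
    "EnumerationRecord",
    "enumerate_cms",
    "enumerate_counts",
    "matrix_count",
    "pearson",
    "pcc_curve",
    "sample_counts",
    "sample_cms",
]


def matrix_count(n: int) -> int:
    """Number of confusion matrices with N samples: C(N+3, 3)."""
    return math.comb(n + 3, 3)


def enumerate_cms(n: int) -> Iterator[ConfusionMatrix]:
    """Yield every confusion matrix with exactly *n* samples, once each.

    Iterates the C(n+3, 3) weak compositions of n into (tp, fn, fp, tn)
    in lexicographic order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for tp in range(n + 1):
        for fn in range(n - tp + 1):
            for fp in range(n - tp - fn + 1):
                yield ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=n - tp - fn - fp)


def enumerate_counts(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All matrices of size *n* as four parallel count arrays (vectorized)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    r = np.arange(n + 1)
    tp = r[:, None, None]
    fn = r[None, :, None]
    fp = r[None, None, :]
    keep = tp + fn + fp <= n  # (n+1)^3 bool mask; ~1 MB at n=100
    shape = keep.shape
    tp_v = np.broadcast_to(tp, shape)[keep]
    fn_v = np.broadcast_to(fn, shape)[keep]
    fp_v = np.broadcast_to(fp, shape)[keep]
    tn_v = n - tp_v - fn_v - fp_v
    return tp_v, fn_v, fp_v, tn_v


def pearson(xs: Iterable[float], ys: Iterable[float]) -> MetricValue:
    """Pearson product-moment correlation via single-pass sufficient stats.

    Accumulates sums in extended precision so the streaming form agrees
    with a centered two-pass computation to ~1e-12 on the metric arrays
    used here.  Zero variance in either argument yields UNDEFINED.
    """
    x = np.asarray(list(xs) if not isinstance(xs, np.ndarray) else xs,
                   dtype=np.float64)
    y = np.asarray(list(ys) if not isinstance(ys, np.ndarray) else ys,
                   dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be 1-D sequences of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two points")
    ld = np.longdouble
    sx, sy = x.sum(dtype=ld), y.sum(dtype=ld)
    sxx = np.multiply(x, x).sum(dtype=ld)
    syy = np.multiply(y, y).sum(dtype=ld)
    sxy = np.multiply(x, y).sum(dtype=ld)
    var_x = n * sxx - sx * sx
    var_y = n * syy - sy * sy
    if var_x <= 0 or var_y <= 0:
        return UNDEFINED
    r = (n * sxy - sx * sy) / np.sqrt(var_x * var_y)
    return float(min(1.0, max(-1.0, float(r))))


@dataclass(frozen=True, slots=True)
class EnumerationRecord:
    """Pairwise metric correlations over all matrices of one sample size.

    ``excluded_count`` is the number of matrices for which BM or MK is
    undefined; such matrices are dropped pairwise from the correlations
    that involve the undefined metric.
    """

    n: int
    matrix_count: int
    pcc_mcc_bm: MetricValue
    pcc_mcc_mk: MetricValue
    pcc_bm_mk: MetricValue
    excluded_count: int


def _record_for(n: int) -> EnumerationRecord:
    tp, fn, fp, tn = enumerate_counts(n)
    mcc = mcc_array(tp, fn, fp, tn)
    bm = bm_array(tp, fn, fp, tn)
    mk = mk_array(tp, fn, fp, tn)
    bm_ok = ~np.isnan(bm)
    mk_ok = ~np.isnan(mk)
    both = bm_ok & mk_ok
    return EnumerationRecord(
        n=n,
        matrix_count=tp.size,
        pcc_mcc_bm=pearson(mcc[bm_ok], bm[bm_ok]),
        pcc_mcc_mk=pearson(mcc[mk_ok], mk[mk_ok]),
        pcc_bm_mk=pearson(bm[both], mk[both]),
        excluded_count=int(np.count_nonzero(~both)),
    )


def pcc_curve(n_values: Sequence[int]) -> list[EnumerationRecord]:
    """Exhaustive PCC(MCC, BM), PCC(MCC, MK), PCC(BM, MK) for each size.

    Each sample size is enumerated in full (vectorized), undefined
    metrics are dropped pairwise, and the three pairwise Pearson
    correlations are computed over the remaining matrices.
    """
    records = []
    for n in n_values:
        if n < 2:
            raise ValueError("pcc_curve requires n >= 2")
        records.append(_record_for(n))
    return records


def sample_counts(count: int, n: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, ...]:
    """*count* uniform random matrices of size *n* as four count arrays.

    Uniform over the C(n+3, 3) weak compositions — the same measure as
    exhaustive enumeration — via the stars-and-bars bijection: three
    distinct bar positions drawn from {1, ..., n+3} map to one
    composition.
    """
    if count < 1 or n < 1:
        raise ValueError("count and n must be >= 1")
    # Draw 3 distinct bar positions per matrix: sample with replacement and
    # redraw the (rare) rows containing duplicates.
    bars = rng.integers(0, n + 3, size=(count, 3))
    while True:
        bars.sort(axis=1)
        dup = (bars[:, 1:] == bars[:, :-1]).any(axis=1)
        if not dup.any():
            break
        bars[dup] = rng.integers(0, n + 3, size=(int(dup.sum()), 3))
    bars = bars + 1
    tp = bars[:, 0] - 1
    fn = bars[:, 1] - bars[:, 0] - 1
    fp = bars[:, 2] - bars[:, 1] - 1
    tn = n + 3 - bars[:, 2]
    return tp, fn, fp, tn


def sample_cms(count: int, n: int, seed: int | np.random.Generator) -> Iterator[ConfusionMatrix]:
    """Stream *count* uniform random confusion matrices of size *n*.

    Reproducible: the same seed yields the identical stream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tp, fn, fp, tn = sample_counts(count, n, rng)
    for values in zip(tp.tolist(), fn.tolist(), fp.tolist(), tn.tolist()):
        yield ConfusionMatrix(*values)
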