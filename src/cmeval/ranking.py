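"""Ranking classifiers by a chosen metric.

The ranking metric matters: because MCC folds in prevalence while BM
does not, two classifiers evaluated on datasets of different prevalence
can rank in opposite orders under MCC and BM.  UNDEFINED metric values
are never ordered against numbers; they are placed last and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .fixtures import NamedClassifierResult
from .metrics import MetricPanel
from .types import MetricValue, is_defined

__all__ = ["RankEntry", "Ranking", "rank_classifiers", "rank_by_values", "RANKABLE_METRICS"]

RANKABLE_METRICS = (
    "mcc", "ba", "bm", "mk", "accuracy", "f1", "tpr", "tnr", "ppv", "npv",
)


@dataclass(frozen=True, slots=True)
class RankEntry:
    rank: int
    name: str
    value: MetricValue
    undefined: bool


@dataclass(frozen=True, slots=True)
class Ranking:
    """Descending order under one metric, with tie groups.

    Ties share a (competition) rank; ``tie_groups`` lists every group of
    two or more classifiers with exactly equal values.  Entries whose
    metric is UNDEFINED come last, flagged, with no rank competition.
    """

    metric: str
    entries: tuple[RankEntry, ...]
    tie_groups: tuple[tuple[str, ...], ...]

    @property
    def top(self) -> RankEntry:
        return self.entries[0]


def rank_by_values(named_values: Sequence[tuple[str, MetricValue]],
                   metric: str) -> Ranking:
    """Rank (name, value) pairs descending; stable for equal values."""
    if not named_values:
        raise ValueError("nothing to rank")
    defined = [(name, v) for name, v in named_values if is_defined(v)]
    undefined = [(name, v) for name, v in named_values if not is_defined(v)]
    # Stable sort keeps input order within ties.
    defined.sort(key=lambda item: -item[1])

    entries: list[RankEntry] = []
    groups: list[tuple[str, ...]] = []
    i = 0
    while i < len(defined):
        j = i
        while j < len(defined) and defined[j][1] == defined[i][1]:
            j += 1
        group = defined[i:j]
        for name, value in group:
            entries.append(RankEntry(rank=i + 1, name=name, value=value,
                                     undefined=False))
        if len(group) > 1:
            groups.append(tuple(name for name, _ in group))
        i = j
    next_rank = len(defined) + 1
    for name, value in undefined:
        entries.append(RankEntry(rank=next_rank, name=name, value=value,
                                 undefined=True))
    return Ranking(metric=metric, entries=tuple(entries),
                   tie_groups=tuple(groups))


def _extract(panel: MetricPanel | Mapping[str, MetricValue],
             metric: str) -> MetricValue:
    if isinstance(panel, Mapping):
        return panel[metric]
    return panel[metric]


def rank_classifiers(results: Sequence[NamedClassifierResult | tuple],
                     metric: str) -> Ranking:
    """Rank named classifier results by *metric*, descending.

    Accepts :class:`NamedClassifierResult` objects or plain
    ``(name, panel)`` pairs where the panel is a
    :class:`~cmeval.metrics.MetricPanel` or a metric-name mapping (e.g.
    published metric tables whose matrices are unavailable).
    """
    if metric not in RANKABLE_METRICS:
        raise ValueError(f"metric must be one of {RANKABLE_METRICS}, got {metric!r}")
    if not results:
        raise ValueError("nothing to rank")
    named_values = []
    for item in results:
        if isinstance(item, NamedClassifierResult):
            named_values.append((item.name, item.panel[metric]))
        else:
            name, panel = item
            named_values.append((name, _extract(panel, metric)))
    return rank_by_values(named_values, metric)
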