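"""Known-randomness simulator: classifiers that cheat a known amount.

The model is an exam of n yes/no questions.  Reference answers are
positive with probability phi (the prevalence).  The student copies a
fraction ``lookup`` of the answers verbatim — a uniformly random subset
of exactly round(lookup * n) items — and guesses the rest, answering
positive with probability ``guess_bias`` independently per item.

Under this model

    E[TPR] = lookup + (1 - lookup) * guess_bias
    E[TNR] = lookup + (1 - lookup) * (1 - guess_bias)

so E[BM] = E[TPR] + E[TNR] - 1 = lookup, whatever phi and guess_bias
are: bookmaker informedness recovers the informed fraction exactly, and
the randomness index 1 - |BM| recovers the guessed fraction.  MCC and MK
carry the prefactors sqrt((phi - phi^2)/(beta - beta^2)) and its
reciprocal and therefore drift away from the lookup fraction whenever
prevalence and prediction bias are dissimilar — they are not reliable
measures of how random a classifier is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ConfusionMatrix, cm_from_labels
from .metrics import bookmaker, markedness, mcc
from .types import UNDEFINED, MetricValue, is_defined

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_replicate",
    "run_simulation",
    "randomness_grid",
    "estimate_randomness",
]


@dataclass(frozen=True, slots=True)
class SimulationConfig:
    """Parameters of the known-randomness simulation.

    ``fixed_counts`` draws exactly round(phi * n) reference positives
    instead of independent Bernoulli(phi) labels.  ``bias_is_overall``
    reinterprets ``guess_bias`` as the target *overall* share of
    positive predictions (beta); the per-item guess probability is then
    solved from beta = lookup * phi + (1 - lookup) * b and clipped to
    [0, 1].  Defaults: fluctuating prevalence, bias of the guessed
    portion only.
    """

    n: int
    phi: float
    lookup: float
    guess_bias: float
    reps: int = 1
    seed: int = 0
    fixed_counts: bool = False
    bias_is_overall: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for name in ("phi", "lookup", "guess_bias"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")

    @property
    def guess_probability(self) -> float:
        """Per-item positive-guess probability for the random portion."""
        if not self.bias_is_overall:
            return self.guess_bias
        if self.lookup >= 1.0:
            return 0.0  # nothing is guessed
        b = (self.guess_bias - self.lookup * self.phi) / (1.0 - self.lookup)
        return min(1.0, max(0.0, b))


def simulate_replicate(config: SimulationConfig,
                       rng: np.random.Generator) -> ConfusionMatrix:
    """One simulated exam: reference labels, copied subset, random rest."""
    n = config.n
    if config.fixed_counts:
        n_pos = round(config.phi * n)
        reference = np.zeros(n, dtype=bool)
        reference[rng.permutation(n)[:n_pos]] = True
    else:
        reference = rng.random(n) < config.phi
    predicted = rng.random(n) < config.guess_probability
    n_copy = round(config.lookup * n)
    if n_copy:
        copied = rng.permutation(n)[:n_copy]
        predicted[copied] = reference[copied]
    return cm_from_labels(reference, predicted)


@dataclass(frozen=True, slots=True)
class SimulationResult:
    """Per-replicate metrics and their summaries for one configuration.

    Replicates where BM (equivalently MK) is undefined — a reference or
    prediction class absent, possible at extreme phi and small n — are
    excluded from the means and counted in ``excluded``.
    """

    config: SimulationConfig
    bm: tuple[MetricValue, ...]
    mcc: tuple[float, ...]
    mk: tuple[MetricValue, ...]
    beta: tuple[float, ...]
    excluded: int

    def _defined(self, values) -> np.ndarray:
        return np.array([v for v in values if is_defined(v)], dtype=float)

    def _summary(self, values) -> tuple[float, float, float]:
        arr = self._defined(values)
        if arr.size == 0:
            return (math.nan, math.nan, math.nan)
        std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return (float(arr.mean()), std, std / math.sqrt(arr.size))

    @property
    def bm_mean(self) -> float:
        return self._summary(self.bm)[0]

    @property
    def bm_se(self) -> float:
        return self._summary(self.bm)[2]

    @property
    def mcc_mean(self) -> float:
        return self._summary(self.mcc)[0]

    @property
    def mcc_se(self) -> float:
        return self._summary(self.mcc)[2]

    @property
    def mk_mean(self) -> float:
        return self._summary(self.mk)[0]

    @property
    def mk_se(self) -> float:
        return self._summary(self.mk)[2]

    def as_row(self) -> dict[str, float]:
        bm_m, bm_s, bm_e = self._summary(self.bm)
        mcc_m, mcc_s, mcc_e = self._summary(self.mcc)
        mk_m, mk_s, mk_e = self._summary(self.mk)
        return {
            "n": self.config.n,
            "phi": self.config.phi,
            "lookup": self.config.lookup,
            "guess_bias": self.config.guess_bias,
            "reps": self.config.reps,
            "excluded": self.excluded,
            "bm_mean": bm_m, "bm_std": bm_s, "bm_se": bm_e,
            "mcc_mean": mcc_m, "mcc_std": mcc_s, "mcc_se": mcc_e,
            "mk_mean": mk_m, "mk_std": mk_s, "mk_se": mk_e,
            "beta_mean": float(np.mean(self.beta)),
        }


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run ``config.reps`` independent replicates and summarize them."""
    rng = np.random.default_rng(config.seed)
    bm_vals: list[MetricValue] = []
    mcc_vals: list[float] = []
    mk_vals: list[MetricValue] = []
    beta_vals: list[float] = []
    excluded = 0
    for _ in range(config.reps):
        cm = simulate_replicate(config, rng)
        bm = bookmaker(cm)
        mk = markedness(cm)
        if not (is_defined(bm) and is_defined(mk)):
            excluded += 1
        bm_vals.append(bm)
        mcc_vals.append(mcc(cm))
        mk_vals.append(mk)
        beta_vals.append((cm.tp + cm.fp) / cm.n)
    return SimulationResult(
        config=config,
        bm=tuple(bm_vals),
        mcc=tuple(mcc_vals),
        mk=tuple(mk_vals),
        beta=tuple(beta_vals),
        excluded=excluded,
    )


def randomness_grid(lookups: Sequence[float], phis: Sequence[float],
                    biases: Sequence[float], n: int, reps: int, seed: int,
                    fixed_counts: bool = False,
                    bias_is_overall: bool = False) -> pd.DataFrame:
    """Full factorial lookup x phi x guess_bias grid of simulations.

    One row per cell with mean/std/standard-error of BM, MCC and MK over
    the replicates.  Reproducible: cell seeds are spawned from *seed*.
    """
    cells = [
        (lookup, phi, gbias)
        for lookup in lookups for phi in phis for gbias in biases
    ]
    child_seeds = np.random.SeedSequence(seed).generate_state(len(cells)) % (2**31)
    rows = []
    for (lookup, phi, gbias), cell_seed in zip(cells, child_seeds):
        config = SimulationConfig(
            n=n, phi=phi, lookup=lookup, guess_bias=gbias, reps=reps,
            seed=int(cell_seed), fixed_counts=fixed_counts,
            bias_is_overall=bias_is_overall,
        )
        rows.append(run_simulation(config).as_row())
    return pd.DataFrame(rows)


def estimate_randomness(cm: ConfusionMatrix) -> MetricValue:
    """Randomness index 1 - |BM| of an observed matrix.

    For a classifier from the known-randomness model this estimates
    1 - lookup, the guessed fraction; UNDEFINED when BM is.
    """
    bm = bookmaker(cm)
    if not is_defined(bm):
        return UNDEFINED
    return 1.0 - abs(bm)
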