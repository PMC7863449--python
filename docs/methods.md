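# Methods

## Scope and model

`cmeval` treats the two-class confusion matrix `(TP, FN, FP, TN)` as the
primary object of binary-classification evaluation.  Everything the
package computes is a deterministic function of those four counts (or of
the equivalent rate-space coordinates), with two stochastic components:
uniform sampling of the matrix space and the known-randomness
simulator.  Threshold selection, ROC/PR curves and AUC, multi-class
matrices, and uncertainty quantification of metrics from finite samples
are deliberately out of scope.

## Undefined-value semantics

The basic rates have the shape `x/(x+y)`.  At `(x, y) → (0, 0)` the
limit depends on the approach path (0 along `x = 0`, 1 along `y = 0`,
any `t ∈ (0,1)` along `y = x(1−t)/t`), so no substitute value is
defensible.  `cmeval` therefore represents such values by a singleton
`UNDEFINED` that

- absorbs arithmetic (`1 − UNDEFINED` is `UNDEFINED`), so derived
  metrics like `BM = TPR + TNR − 1` become undefined exactly when an
  ingredient is;
- raises a typed error on ordering comparisons and numeric coercion, so
  an undefined value can never silently win or lose a ranking;
- serializes as the literal string `undefined` in CSV and reports.

Consequences: BA and BM are undefined iff `(TP+FN)(TN+FP) = 0`, MK iff
`(TP+FP)(TN+FN) = 0`, F1 iff PPV or TPR is undefined or both are zero.
Denominators of integer counts are compared to exactly 0; for relative
matrices the share-sum invariant is enforced at 1e-9.

**MCC is the exception.**  Its zero-denominator cases admit a standard
total extension, and the dominant convention in existing metric
implementations is to return 0 there.  `cmeval` follows that convention
(so MCC never excludes a matrix from an analysis) and flags the
substitution via `MetricPanel.mcc_degenerate` — including for the
perfect-degenerate matrices `tp = N` and `tn = N`, where 0 is
unintuitive but keeps the function total and the convention uniform.

## Numerical choices

- MCC is computed as `(TP·TN − FP·FN)/√(product of margins)` with the
  products formed in exact integer arithmetic before the final square
  root; vectorized versions promote to float64 first (the margin
  product of an int64 array would overflow near N ~ 10⁵).
- Identity checks use an absolute tolerance of 1e-10 on metrics of
  magnitude ≤ 1.  All identities are smooth rational/radical functions
  of the counts, so double precision leaves ~5 orders of headroom.
  Identities whose ingredients are undefined on a degenerate matrix are
  reported as *not applicable* rather than failed.
- The geometric-mean form `MCC = ±√(BM·MK)` takes its sign from BM
  (equivalently MK): the prefactor relations guarantee all three share
  a sign, and inputs of strictly opposite sign raise an error.
- Converting shares to counts uses largest-remainder rounding, which
  always preserves the total N; a warning is emitted when any entry had
  to move by ≥ 0.5, since the counts then only approximate the shares.
- When prevalence is exactly 0 or 1, the rate of the absent class is
  non-identifiable; `rates_from_cm` records it as NaN and
  `cm_from_rates` ignores it.  Round-trips are exact for every matrix
  with both reference classes present.
- The streaming Pearson correlation accumulates the five sufficient
  sums in extended (long-double) precision, which keeps it within
  1e-12 of a centered two-pass computation on the metric arrays used
  here (|values| ≤ 1, up to ~2·10⁵ points).

## Enumeration and the correlation curve

For sample size N the C(N+3,3) matrices are generated as weak
compositions of N (a lexicographic generator for object streams; a
vectorized mask construction for the correlation curve).  Per N, MCC,
BM and MK are evaluated for all matrices and the three pairwise Pearson
correlations computed.

**Exclusion policy** (a genuinely open design point): a matrix is
dropped from a pairwise correlation only when one of that pair's
metrics is undefined (pairwise deletion); MCC, being total, never
causes exclusion.  The per-N record reports `excluded_count` (matrices
with BM or MK undefined) for transparency.  Pairwise deletion preserves
the transpose symmetry `fn ↔ fp`, which maps BM to MK while fixing MCC;
PCC(MCC, BM) = PCC(MCC, MK) therefore holds exactly, and the equality
is tested at 1e-9.  Under this policy the PCC(MCC, BM) curve over
N ∈ [5, 100] is non-monotone with its minimum at N = 22 — "around
N ≈ 25"; the exact minimizer depends on the exclusion policy, so the
tests assert the neighborhood, not the point.

**Random sampling** draws uniformly over the compositions (the same
measure as the enumeration) via the stars-and-bars bijection: three
distinct bar positions out of N+3, sampled with replacement and
redrawn on the rare collision.  The default scatter workload (10⁵
matrices of size 4·10⁴) is a scaled-down stand-in for multi-million
clouds; the qualitative features (sign concordance, envelope, width)
appear already at this size.

## Known-randomness simulator

Reference labels are independent Bernoulli(φ) draws, so the realized
prevalence fluctuates (a `fixed_counts` option pins it to
`round(φ·n)`).  The copied subset is a uniformly random subset of
exactly `round(lookup·n)` items — per-item Bernoulli copying would
inflate the variance of BM without changing its mean.  The guessed
items are positive independently with probability `guess_bias`.

Under this model `E[TPR] = lookup + (1−lookup)·b` and
`E[TNR] = lookup + (1−lookup)·(1−b)`, hence `E[BM] = lookup` exactly,
for every φ and b.  The simulation tests verify this recovery within
three Monte-Carlo standard errors, and verify that mean MCC deviates
from the lookup fraction by more than three standard errors in
φ/β-dissimilar cells — the behavior that disqualifies MCC and MK as
randomness measures.

**Bias semantics** is ambiguous in principle: the stated bias can
target the guessed portion only (default) or the overall share of
positive predictions.  Both are implemented; `bias_is_overall=True`
solves `β = lookup·φ + (1−lookup)·b` for the per-item guess probability
and clips it to [0, 1].  Replicates where a reference or prediction
class is entirely absent (possible at extreme φ with small n) have
undefined BM/MK; they are excluded from the summary means and counted.

Default study conditions: n = 10⁵ items, 100 replicates per cell,
lookup ∈ {0.25, 0.5, 0.75}, φ and guess bias ∈ {0.05, 0.5, 0.95}.  At
these sizes the Monte-Carlo standard error of mean BM is ~10⁻⁴, small
enough that the recovery check is sharp.  Unit tests use reduced sizes
(n = 2·10⁴, 25–50 replicates) with correspondingly wider bands.

## Fixtures and published tables

The bundled worked examples store the printed *count* matrices; their
relative forms are derived exactly (counts/N) and compared to the
published share matrices at relative tolerance 2e-3, because the
published shares are truncated to about three significant figures and
do not sum exactly to 1.  The published four-classifier benchmark table
(decision tree, radial SVM, k-NN, naive Bayes on gene-expression data)
is used only as a *ranking input*: retraining those classifiers
requires external data and stochastic fits, so the ranking mechanics
are exercised on the printed metric rows, and on the two-classifier
fixtures whose matrices are printed in full.

Ranking is descending with competition ranks; exactly equal values form
a reported tie group (input order breaks the tie in the listing), and
UNDEFINED entries are appended last and flagged rather than ordered.

## What the synthetic generators do and do not show

The enumeration and composition sampler cover the *space of matrices*
uniformly, which is the right measure for questions about the metrics
as functions; it is not the distribution of matrices any particular
classifier family produces.  The randomness simulator emulates
label-copying with independent guessing; real classifiers' errors are
typically correlated with inputs, so passing recovery tests here shows
the metric algebra behaves as derived, not that BM estimates "percent
informed" for arbitrary real models.  Finite-sample uncertainty of the
metrics is intentionally not quantified anywhere.

## Problem sizes used by the test suite

Exhaustive checks run over all matrices with N ≤ 30 (46,376 matrices)
for identities and oracle equivalence, N ≤ 20 for round-trips, and
N ∈ [5, 100] for the correlation curve; large-sample checks use 10,000
random matrices of size 40,000.  These sizes make every suite-level
claim checkable in seconds while covering all degeneracy classes
(empty rows, empty columns, boundary prevalence) exhaustively.
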