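# cmeval — two-class confusion-matrix evaluation

`cmeval` is a toolkit for evaluating binary classifications from their
confusion matrix — the 2×2 table of true positives (TP), false
negatives (FN), false positives (FP) and true negatives (TN).  It is
aimed at anyone who has to pick, report or compare a single-number
summary of a classifier: bioinformaticians benchmarking predictors,
epidemiologists reasoning about diagnostic tests, and machine-learning
practitioners comparing published results.

## What it computes

**Rates and metrics** with exact undefined-value semantics:

- basic rates TPR (sensitivity), TNR (specificity), PPV (precision),
  NPV and their complements FNR, FPR, FDR, FOR;
- Matthews correlation coefficient
  `MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))`,
  extended to 0 on matrices with an empty margin (and flagged);
- balanced accuracy `BA = (TPR+TNR)/2`, bookmaker informedness
  `BM = TPR+TNR−1` (Youden's J), markedness `MK = PPV+NPV−1`,
  accuracy and F1.

A rate with a vanishing denominator has no limit value, so it is
represented by a distinguished `UNDEFINED` state that propagates through
arithmetic and refuses ordering comparisons — never silently replaced
by 0 or 0.5.

**The prevalence/bias reparameterization.**  A matrix of size N is
losslessly described by (N, φ, TPR, TNR), where φ = (TP+FN)/N is the
prevalence and β = (TP+FP)/N the prediction bias.  `cmeval` converts in
both directions and evaluates the Bayes-rule predictive values
`PPV = TPR·φ / (TPR·φ + (1−TNR)(1−φ))` (and NPV, and their inverses).

**Inter-metric identities**, checked numerically at 1e-10:
`BA = (BM+1)/2`, the product form
`MCC = √(PPV·TPR·TNR·NPV) − √(FDR·FNR·FPR·FOR)`, the prefactor
relations `MCC = √((φ−φ²)/(β−β²))·BM = √((β−β²)/(φ−φ²))·MK`, and the
geometric-mean form `MCC = ±√(BM·MK)`.

**Enumeration.**  All C(N+3,3) matrices of a sample size N, with
pairwise Pearson correlations between MCC, BM and MK as a function of N,
plus uniform random sampling of matrices for scatter clouds.

**Known-randomness simulation.**  Classifiers that "cheat" a known
lookup fraction of the reference labels and guess the rest: mean BM
recovers the lookup fraction independent of prevalence and bias, which
is why the randomness index `1 − |BM|` — and not MCC or MK — measures
how close a classifier is to random guessing.

## Worked example

```pycon
>>> from cmeval import ConfusionMatrix, metric_panel
>>> cm = ConfusionMatrix(tp=100, fn=1, fp=5000, tn=94900)
>>> panel = metric_panel(cm)
>>> print({k: panel.formatted()[k] for k in ("tpr", "tnr", "ppv", "mcc", "bm", "mk")})
{'tpr': '0.990', 'tnr': '0.950', 'ppv': '0.020', 'mcc': '0.136', 'bm': '0.940', 'mk': '0.020'}
```

This classifier catches 99% of positives and 95% of negatives
(BM = 0.94: objectively well informed), yet MCC is only 0.136 — at
prevalence ~0.001 the precision collapses to 0.02, and MCC is low
whenever *any* of the four basic rates is low.  The same report from the
command line:

```sh
$ cmeval usecase CM1
CM1: [[TP=100 FN=1] [FP=5000 TN=94900]]  (N=100001)
  prevalence phi=0.001  bias beta=0.051
  rates:   TPR=0.990  TNR=0.950  PPV=0.020  NPV=1.000
  metrics: MCC=0.136  BA=0.970  BM=0.940  MK=0.020  ACCURACY=0.950  F1=0.038
  ...
    testing positive    PPV     = 0.020
    testing negative    1 - NPV = 0.00001
    a positive result multiplies the probability by 19.4
```

Other CLI subcommands: `metrics`, `batch`, `rank`, `from-rates`,
`identities`, `enumerate`, `scatter`, `simulate`.  The `examples/`
directory contains one short narrative script per capability.

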