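"""How the predictive values move with prevalence for a fixed classifier.

A classifier is fully described by TPR and TNR; PPV and NPV additionally
depend on the dataset's prevalence phi.  With TPR=0.9 and TNR=0.8
(BM = 0.7), PPV climbs and NPV falls as phi grows: at least one of the
two predictive values is always high, but which one depends entirely on
the dataset, not the classifier.
"""

import numpy as np

from cmeval import npv_from_rates, ppv_from_rates

TPR, TNR = 0.9, 0.8

print(f"classifier: TPR={TPR}  TNR={TNR}  (BM = {TPR + TNR - 1:.1f})")
print(f"{'phi':>6} {'PPV':>8} {'NPV':>8}")
for phi in np.arange(0.1, 1.0, 0.1):
    ppv = ppv_from_rates(TPR, TNR, phi)
    npv = npv_from_rates(TPR, TNR, phi)
    print(f"{phi:>6.1f} {ppv:>8.3f} {npv:>8.3f}")

# The screening regime: excellent rates, 1-in-1000 prevalence.
ppv = ppv_from_rates(0.99, 0.95, 0.001)
print(f"\nscreening (TPR=0.99, TNR=0.95, phi=0.001): PPV = {ppv:.3f}")
print(f"a positive test multiplies the pre-test probability by {ppv / 0.001:.1f},")
print("yet a positive subject is still unlikely to be a true positive.")
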