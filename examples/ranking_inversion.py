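"""Why MCC cannot compare classifiers across datasets.

Classifier A is published on a balanced dataset (phi = 0.5), classifier
B on an imbalanced one (phi = 0.05).  B has strictly better TPR and TNR,
yet A has the higher MCC, because MCC folds in the dataset's prevalence.
Ranking by BM — which depends on the classifier alone — puts B first.
"""

from cmeval import load_fixture, rank_classifiers, use_case_report

print(use_case_report("UC4_separate"))
print("-" * 72)

# Both classifiers evaluated on both datasets: B wins everywhere.
crossed = load_fixture("UC4_crossed")
for metric in ("mcc", "bm"):
    ranking = rank_classifiers(crossed, metric)
    order = "  ".join(f"{e.rank}. {e.name} ({e.value:.3f})" for e in ranking.entries)
    print(f"{metric.upper():>4} ranking (both on both datasets): {order}")
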