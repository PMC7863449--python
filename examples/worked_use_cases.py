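"""Three single-classifier scenarios where MCC, BM, BA and MK disagree.

Each report prints the count matrix, the full metric panel, the numeric
identity checks, and a scenario-specific observation.  The point: MCC is
low whenever any of TPR/TNR/PPV/NPV is low, while BA/BM (reference side)
and MK (prediction side) can each look excellent on the same matrix.
"""

from cmeval import use_case_report

for name in ("CM1", "CM2", "CM3"):
    print(use_case_report(name))
    print("-" * 72)
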