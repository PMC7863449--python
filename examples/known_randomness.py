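"""Simulated classifiers with a known amount of randomness.

Students answer n yes/no questions: a `lookup` fraction is copied from
the answer key, the rest is guessed positive with probability `bias`.
Mean BM recovers the lookup fraction in every cell regardless of
prevalence and bias; mean MCC and MK drift whenever prevalence and
prediction bias are dissimilar — so 1 - |BM| (and only it) measures how
much a classifier guesses.
"""

from cmeval import randomness_grid

grid = randomness_grid(
    lookups=[0.25, 0.5, 0.75],
    phis=[0.05, 0.5, 0.95],
    biases=[0.5],
    n=20_000,
    reps=25,
    seed=42,
)

print(f"{'lookup':>7} {'phi':>5} {'bias':>5} {'mean BM':>9} {'mean MCC':>9} {'mean MK':>9}")
for row in grid.itertuples(index=False):
    print(f"{row.lookup:>7.2f} {row.phi:>5.2f} {row.guess_bias:>5.2f} "
          f"{row.bm_mean:>9.3f} {row.mcc_mean:>9.3f} {row.mk_mean:>9.3f}")

print("\nmean BM tracks the lookup fraction in every row; MCC and MK only")
print("do so when prevalence matches the prediction bias (phi ~ 0.5 here).")
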