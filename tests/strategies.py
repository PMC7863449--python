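"""Shared hypothesis strategies for confusion matrices."""

from hypothesis import strategies as st

from cmeval import ConfusionMatrix

counts = st.integers(min_value=0, max_value=500)


def confusion_matrices(min_total: int = 1):
    return (
        st.tuples(counts, counts, counts, counts)
        .filter(lambda t: sum(t) >= min_total)
        .map(lambda t: ConfusionMatrix(*t))
    )


def nondegenerate_matrices():
    """Matrices where every margin is positive (all metrics defined)."""
    return confusion_matrices().filter(
        lambda cm: min(cm.tp + cm.fn, cm.tn + cm.fp, cm.tp + cm.fp, cm.tn + cm.fn) > 0
    )
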