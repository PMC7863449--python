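"""Rates, multi-category metrics and undefined-value semantics."""

import math

import numpy as np
import pytest
from hypothesis import given
from sklearn.metrics import matthews_corrcoef

from cmeval import (
    UNDEFINED,
    ConfusionMatrix,
    UndefinedComparisonError,
    accuracy,
    balanced_accuracy,
    basic_rates,
    bookmaker,
    cm_from_labels,
    f1,
    format_value,
    is_defined,
    labels_from_cm,
    markedness,
    mcc,
    metric_panel,
    swap_labels,
)
from cmeval.enumeration import enumerate_cms
from strategies import confusion_matrices, nondegenerate_matrices


class TestBasicRates:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            # High-sensitivity screening test on an imbalanced cohort.
            (ConfusionMatrix(100, 1, 5000, 94900),
             dict(tpr=100 / 101, tnr=94900 / 99900, ppv=100 / 5100, npv=94900 / 94901)),
            (ConfusionMatrix(50, 0, 0, 50), dict(tpr=1.0, tnr=1.0, ppv=1.0, npv=1.0)),
            (ConfusionMatrix(0, 0, 3, 7),
             dict(tpr=UNDEFINED, tnr=0.7, ppv=0.0, npv=1.0)),
        ],
    )
    def test_defining_ratios(self, cm, expected):
        rates = basic_rates(cm)
        for name, value in expected.items():
            got = getattr(rates, name)
            if value is UNDEFINED:
                assert got is UNDEFINED
            else:
                assert got == pytest.approx(value, abs=1e-15)

    def test_screening_example_rounds_to_published_rates(self):
        rates = basic_rates(ConfusionMatrix(100, 1, 5000, 94900))
        assert round(rates.tpr, 2) == 0.99
        assert round(rates.tnr, 2) == 0.95

    @given(confusion_matrices())
    def test_complements_defined_iff_base_rate_is(self, cm):
        r = basic_rates(cm)
        for base, comp in [(r.tpr, r.fnr), (r.tnr, r.fpr), (r.ppv, r.fdr), (r.npv, r.for_)]:
            assert is_defined(base) == is_defined(comp)
            if is_defined(base):
                assert comp == pytest.approx(1 - base, abs=1e-15)


class TestMcc:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            (ConfusionMatrix(100, 1, 5000, 94900), 0.136),
            (ConfusionMatrix(90000, 10000, 1, 9), 0.027),
            (ConfusionMatrix(90000, 0, 10, 1), 0.301),
            (ConfusionMatrix(25, 25, 25, 25), 0.0),
        ],
    )
    def test_published_values(self, cm, expected):
        assert round(mcc(cm), 3) == expected

    @pytest.mark.parametrize(
        "cm",
        [
            ConfusionMatrix(10, 0, 0, 0),   # tp = N
            ConfusionMatrix(0, 0, 0, 10),   # tn = N
            ConfusionMatrix(0, 5, 0, 5),    # no positive predictions
            ConfusionMatrix(5, 0, 5, 0),    # no negative predictions
        ],
    )
    def test_total_extension_on_degenerate_matrices(self, cm):
        assert mcc(cm) == 0.0
        assert metric_panel(cm).mcc_degenerate

    def test_nondegenerate_matrices_not_flagged(self):
        assert not metric_panel(ConfusionMatrix(1, 1, 1, 1)).mcc_degenerate

    @given(confusion_matrices())
    def test_agrees_with_sklearn_on_label_vectors(self, cm):
        if metric_panel(cm).mcc_degenerate:
            return
        ref, pred = labels_from_cm(cm)
        assert mcc(cm) == pytest.approx(
            matthews_corrcoef(ref.astype(int), pred.astype(int)), abs=1e-12
        )

    def test_equals_pearson_correlation_of_labels_exhaustively(self):
        # Independent oracle: the sample correlation of the two
        # reconstructed binary label vectors.
        for n in range(1, 13):
            for cm in enumerate_cms(n):
                if metric_panel(cm).mcc_degenerate:
                    assert mcc(cm) == 0.0
                    continue
                ref, pred = labels_from_cm(cm)
                r = np.corrcoef(ref.astype(float), pred.astype(float))[0, 1]
                assert mcc(cm) == pytest.approx(r, abs=1e-12)


class TestInformednessAndMarkedness:
    def test_high_tp_low_tn_example(self):
        # Almost all reference positives are caught, so BA/BM look
        # excellent, but the negative predictions are worthless.
        cm = ConfusionMatrix(90000, 10000, 1, 9)
        assert balanced_accuracy(cm) == pytest.approx(0.9)
        assert bookmaker(cm) == pytest.approx(0.8)
        assert round(markedness(cm), 3) == 0.001

    def test_undefined_when_reference_class_missing(self):
        cm = ConfusionMatrix(5, 5, 0, 0)  # no reference negatives
        assert balanced_accuracy(cm) is UNDEFINED
        assert bookmaker(cm) is UNDEFINED
        # Both prediction margins are populated, so MK is still defined.
        assert markedness(cm) == 0.0
        # With no negative predictions at all, MK loses its NPV term.
        assert markedness(ConfusionMatrix(5, 0, 5, 0)) is UNDEFINED

    def test_bm_defined_iff_both_reference_classes_present(self):
        assert is_defined(bookmaker(ConfusionMatrix(1, 0, 0, 1)))
        assert bookmaker(ConfusionMatrix(0, 0, 3, 7)) is UNDEFINED


class TestAccuracyF1:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(50, 0, 0, 50)
        assert accuracy(cm) == 1.0
        assert f1(cm) == 1.0

    def test_f1_undefined_when_precision_is(self):
        cm = ConfusionMatrix(0, 10, 0, 10)
        assert accuracy(cm) == 0.5
        assert f1(cm) is UNDEFINED

    @given(nondegenerate_matrices())
    def test_count_form_equals_prevalence_weighted_rates(self, cm):
        r = basic_rates(cm)
        phi = (cm.tp + cm.fn) / cm.n
        assert accuracy(cm) == pytest.approx(
            r.tpr * phi + r.tnr * (1 - phi), abs=1e-12
        )


class TestPanelAndSwap:
    def test_panel_matches_single_metric_operations(self):
        cm = ConfusionMatrix(100, 1, 5000, 94900)
        panel = metric_panel(cm)
        assert panel.mcc == mcc(cm)
        assert panel.bm == bookmaker(cm)
        assert panel.ba == balanced_accuracy(cm)
        assert panel.mk == markedness(cm)
        assert panel.f1 == f1(cm)
        assert round(panel.mcc, 3) == 0.136
        assert round(panel.bm, 2) == 0.94

    def test_all_positive_matrix_panel(self):
        panel = metric_panel(ConfusionMatrix(10, 0, 0, 0))
        assert panel.tpr == 1.0
        assert panel.ppv == 1.0
        assert panel.tnr is UNDEFINED
        assert panel.npv is UNDEFINED
        assert panel.bm is UNDEFINED
        assert panel.mk is UNDEFINED

    def test_swap_is_involution_and_symmetric_fixed_point(self):
        cm = ConfusionMatrix(3, 7, 7, 3)
        assert swap_labels(cm) == cm
        cm = ConfusionMatrix(1, 2, 3, 4)
        assert swap_labels(swap_labels(cm)) == cm

    def test_swapped_uc2_matches_uc1_structure(self):
        cm2 = ConfusionMatrix(90000, 10000, 1, 9)
        swapped = swap_labels(cm2)
        assert swapped == ConfusionMatrix(9, 1, 10000, 90000)
        assert round(mcc(swapped), 3) == round(mcc(cm2), 3) == 0.027

    @given(confusion_matrices())
    def test_swap_invariance_of_class_symmetric_metrics(self, cm):
        swapped = swap_labels(cm)
        assert mcc(cm) == pytest.approx(mcc(swapped), abs=1e-12)
        for metric in (balanced_accuracy, bookmaker, markedness):
            a, b = metric(cm), metric(swapped)
            if is_defined(a) and is_defined(b):
                assert a == pytest.approx(b, abs=1e-12)
            else:
                assert a is UNDEFINED and b is UNDEFINED


class TestRangesAndSigns:
    @given(confusion_matrices())
    def test_defined_metrics_stay_in_range(self, cm):
        panel = metric_panel(cm)
        for name in ("mcc", "bm", "mk"):
            value = panel[name]
            if is_defined(value):
                assert -1 - 1e-12 <= value <= 1 + 1e-12
        for name in ("tpr", "tnr", "ppv", "npv", "ba", "accuracy", "f1"):
            value = panel[name]
            if is_defined(value):
                assert -1e-12 <= value <= 1 + 1e-12

    @given(nondegenerate_matrices())
    def test_mcc_bm_mk_share_sign(self, cm):
        panel = metric_panel(cm)
        signs = {math.copysign(1, v) for v in (panel.mcc, panel.bm, panel.mk)
                 if abs(v) > 1e-12}
        assert len(signs) <= 1


class TestLabels:
    def test_hand_counted_example(self):
        cm = cm_from_labels([1, 1, 0], [1, 0, 0])
        assert cm == ConfusionMatrix(tp=1, fn=1, fp=0, tn=1)

    def test_identical_vectors_make_no_errors(self):
        cm = cm_from_labels([1, 0, 1, 1], [1, 0, 1, 1])
        assert cm.fn == cm.fp == 0

    def test_counts_conserved(self, rng):
        ref = rng.integers(0, 2, size=1000)
        pred = rng.integers(0, 2, size=1000)
        cm = cm_from_labels(ref, pred)
        assert cm.n == 1000
        assert cm.tp + cm.fn == int(ref.sum())

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            cm_from_labels([1, 0], [1])
        with pytest.raises(ValueError):
            cm_from_labels([1, 2], [0, 1])

    def test_roundtrip_through_label_vectors(self):
        cm = ConfusionMatrix(3, 4, 5, 6)
        assert cm_from_labels(*labels_from_cm(cm)) == cm


class TestUndefinedSemantics:
    def test_arithmetic_absorbs(self):
        assert UNDEFINED + 1 is UNDEFINED
        assert 1 - UNDEFINED is UNDEFINED
        assert UNDEFINED * 0.5 is UNDEFINED
        assert 2 / UNDEFINED is UNDEFINED
        assert -UNDEFINED is UNDEFINED
        assert abs(UNDEFINED) is UNDEFINED

    def test_ordering_raises(self):
        with pytest.raises(UndefinedComparisonError):
            UNDEFINED < 0.5
        with pytest.raises(UndefinedComparisonError):
            bool(UNDEFINED)
        with pytest.raises(UndefinedComparisonError):
            float(UNDEFINED)

    def test_serialization(self):
        assert format_value(UNDEFINED) == "undefined"
        assert format_value(0.13579, 3) == "0.136"
        assert repr(UNDEFINED) == "undefined"

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 5)
        with pytest.raises(ValueError):
            ConfusionMatrix(0, 0, 0, 0)
        with pytest.raises(TypeError):
            ConfusionMatrix(0.5, 0, 0, 5)
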