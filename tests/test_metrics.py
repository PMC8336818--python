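"""Metric machinery against brute-force oracles and worked arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periharm.metrics import (ConfusionMatrix2x2, attribute_metrics,
                              classification_report, cohen_kappa,
                              likelihood_ratios, match_spans,
                              pairwise_agreement, post_test_probability,
                              reconstruct_confusion, span_metrics)
from periharm.textmodel import Mention


# --- independent brute-force oracles ---------------------------------------


def brute_prf(gold, pred):
    classes = sorted(set(gold) | set(pred))
    per = {}
    for c in classes:
        tp = sum(g == c and p == c for g, p in zip(gold, pred))
        fp = sum(g != c and p == c for g, p in zip(gold, pred))
        fn = sum(g == c and p != c for g, p in zip(gold, pred))
        prec = tp / (tp + fp) if tp + fp else float("nan")
        rec = tp / (tp + fn) if tp + fn else float("nan")
        f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
        per[c] = (prec, rec, f)
    micro = sum(g == p for g, p in zip(gold, pred)) / len(gold)
    gold_classes = sorted(set(gold))

    def _mean_defined(vals):
        kept = [v for v in vals if not math.isnan(v)]
        return sum(kept) / len(kept) if kept else float("nan")

    macro = tuple(
        _mean_defined([per[c][i] for c in gold_classes]) for i in range(3)
    )
    return per, micro, macro


def brute_kappa(a, b):
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    labels = set(a) | set(b)
    pe = sum((a.count(l) / n) * (b.count(l) / n) for l in labels)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def _m(cs, ce, **attrs):
    return Mention(0, 0, char_start=cs, char_end=ce, **attrs)


# --- span matching ----------------------------------------------------------


class TestMatchSpans:
    def test_exact_match(self):
        pairs, cm = match_spans([_m(4, 15)], [_m(4, 15)], "exact")
        assert len(pairs) == 1 and (cm.tp, cm.fp, cm.fn) == (1, 0, 0)

    def test_partial_overlap_by_mode(self):
        gold, pred = [_m(0, 20)], [_m(0, 12)]
        _, exact = match_spans(gold, pred, "exact")
        assert (exact.tp, exact.fp, exact.fn) == (0, 1, 1)
        _, overlap = match_spans(gold, pred, "overlap")
        assert (overlap.tp, overlap.fp, overlap.fn) == (1, 0, 0)

    def test_longest_overlap_tie_break(self):
        gold = [_m(0, 10)]
        pred = [_m(9, 11), _m(0, 8)]
        pairs, _ = match_spans(gold, pred, "overlap")
        assert pairs[0][1].char_start == 0

    def test_empty_empty_convention(self):
        _, cm = match_spans([], [], "exact")
        assert span_metrics(cm) == {"precision": 1.0, "recall": 1.0, "f": 1.0}

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            match_spans([], [], "fuzzy")

    def test_pairing_is_one_to_one(self):
        gold = [_m(0, 5), _m(0, 5)]
        pred = [_m(0, 5)]
        pairs, cm = match_spans(gold, pred, "exact")
        assert len(pairs) == 1 and cm.fn == 1


# --- classification metrics -------------------------------------------------


class TestClassificationMetrics:
    def test_perfect_agreement_all_ones(self):
        pairs = [(_m(0, 1, polarity="positive"), _m(0, 1, polarity="positive")),
                 (_m(2, 3, polarity="negative"), _m(2, 3, polarity="negative"))]
        rep = attribute_metrics(pairs, "polarity")
        assert rep.micro_f == rep.macro_f == rep.kappa == 1.0

    def test_unknown_attribute_is_programming_error(self):
        with pytest.raises(AttributeError):
            attribute_metrics([], "severity")

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
                    min_size=1, max_size=40))
    def test_oracle_equivalence(self, pairs):
        gold = [g for g, _ in pairs]
        pred = [p for _, p in pairs]
        rep = classification_report(gold, pred)
        per, micro, macro = brute_prf(gold, pred)
        assert rep.micro_precision == pytest.approx(micro)
        assert rep.micro_recall == pytest.approx(micro)
        assert rep.micro_f == pytest.approx(micro)
        assert rep.macro_f == pytest.approx(macro[2], nan_ok=True)
        for c, (prec, rec, f) in per.items():
            got = rep.per_class[c]
            assert got["precision"] == pytest.approx(prec, nan_ok=True)
            assert got["recall"] == pytest.approx(rec, nan_ok=True)
        assert rep.kappa == pytest.approx(brute_kappa(gold, pred), abs=1e-9)

    def test_micro_equals_accuracy_identity(self):
        gold = list("aabbccab")
        pred = list("abbbccaa")
        rep = classification_report(gold, pred)
        acc = sum(g == p for g, p in zip(gold, pred)) / len(gold)
        assert rep.micro_precision == rep.micro_recall == rep.micro_f == acc


class TestKappa:
    def test_identical_mixed_labels(self):
        assert cohen_kappa(list("aabbc"), list("aabbc")) == 1.0

    def test_single_class_identical(self):
        assert cohen_kappa(["a", "a"], ["a", "a"]) == 1.0

    def test_published_patient_level_value(self):
        cm = ConfusionMatrix2x2(tp=20, fp=9, fn=9, tn=114)
        assert round(cm.kappa(), 2) == 0.62

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa(["a"], ["a", "b"])

    def test_random_labels_mean_near_zero(self):
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(400):
            a = rng.integers(0, 2, 30).tolist()
            b = rng.integers(0, 2, 30).tolist()
            vals.append(cohen_kappa(a, b))
        assert abs(float(np.mean(vals))) < 0.02

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from("ab"), st.sampled_from("ab")),
                    min_size=2, max_size=30))
    def test_bounded(self, pairs):
        a = [x for x, _ in pairs]
        b = [y for _, y in pairs]
        assert -1.0 - 1e-9 <= cohen_kappa(a, b) <= 1.0 + 1e-9


# --- diagnostic statistics --------------------------------------------------


class TestReconstruction:
    @pytest.mark.parametrize("args, expected", [
        ((152, 29, 29, 0.69, 0.69), (20, 9, 9, 114)),
        ((152, 29, 46, 0.57, 0.90), (26, 20, 3, 103)),
        ((10, 5, 5, 1.0, 1.0), (5, 0, 0, 5)),
    ])
    def test_reconstruction_arithmetic(self, args, expected):
        cm = reconstruct_confusion(*args)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == expected

    def test_inconsistent_inputs_report_candidates(self):
        with pytest.raises(ValueError, match="TP="):
            reconstruct_confusion(100, 50, 10, 0.90, 0.90)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.integers(1, 40), st.integers(0, 15), st.integers(0, 15),
           st.integers(0, 60))
    def test_roundtrip_identity_to_2dp(self, tp, fp, fn, tn):
        n_total = tp + fp + fn + tn
        n_gold, n_flag = tp + fn, tp + fp
        cm = reconstruct_confusion(n_total, n_gold, n_flag,
                                   round(tp / n_flag, 2), round(tp / n_gold, 2))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)


class TestLikelihoodRatios:
    def test_published_values_with_heuristic(self):
        lr = likelihood_ratios(ConfusionMatrix2x2(20, 9, 9, 114))
        assert round(lr.lr_pos, 1) == 9.4
        assert round(lr.lr_neg, 1) == 0.3

    def test_published_values_without_heuristic(self):
        lr = likelihood_ratios(ConfusionMatrix2x2(26, 20, 3, 103))
        assert round(lr.lr_pos, 1) == 5.5
        assert round(lr.lr_neg, 1) == 0.1

    def test_no_false_positives_flags_infinity(self):
        lr = likelihood_ratios(ConfusionMatrix2x2(4, 0, 7, 48))
        assert math.isinf(lr.lr_pos) and lr.infinite_lr_pos
        assert lr.undefined_ci

    def test_degenerate_gold_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratios(ConfusionMatrix2x2(5, 0, 2, 0))

    def test_lr_pos_increasing_in_sensitivity(self):
        fixed_spec = [likelihood_ratios(ConfusionMatrix2x2(tp, 10, 30 - tp, 90)).lr_pos
                      for tp in (10, 15, 20, 25)]
        assert fixed_spec == sorted(fixed_spec)


class TestPostTestProbability:
    def test_published_post_test_values(self):
        p = 29 / 152
        lr = likelihood_ratios(ConfusionMatrix2x2(20, 9, 9, 114))
        assert round(100 * post_test_probability(p, lr.lr_pos), 1) == 69.0
        assert round(100 * post_test_probability(p, lr.lr_neg), 1) == 7.3

    def test_uninformative_lr(self):
        assert post_test_probability(0.3, 1.0) == pytest.approx(0.3)

    def test_strictly_increasing_in_lr(self):
        vals = [post_test_probability(0.2, lr) for lr in (0.5, 1, 2, 5, 50)]
        assert vals == sorted(vals) and len(set(vals)) == len(vals)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            post_test_probability(0.0, 2.0)
        with pytest.raises(ValueError):
            post_test_probability(0.5, -1.0)


class TestPairwiseAgreement:
    def test_three_annotators_pool_pairs(self):
        labels = {"a": ["x", "y"], "b": ["x", "y"], "c": ["x", "x"]}
        rep = pairwise_agreement(labels)
        # pairs: (a,b) agree 2/2, (a,c) 1/2, (b,c) 1/2 -> micro 4/6
        assert rep.micro_f == pytest.approx(4 / 6)

    def test_needs_two_annotators(self):
        with pytest.raises(ValueError):
            pairwise_agreement({"a": ["x"]})
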