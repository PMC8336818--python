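"""Evaluation battery: span matching, per-attribute micro/macro P/R/F,
Cohen's kappa, service-user confusion matrices, diagnostic likelihood ratios
with log-transform confidence intervals, and post-test probabilities.

Conventions (documented because they matter for sparse clinical corpora):

* empty gold and empty prediction yield span metrics of 1.0;
* a metric with no predicted positives has undefined precision, reported as
  ``nan`` with ``undefined_precision`` flagged in the report;
* attribute metrics are computed over matched span pairs only, so for a
  single-label attribute micro precision = recall = F = accuracy;
* macro averages are unweighted means over the classes present in the gold.

Per-class precision/recall/F and kappa delegate to scikit-learn; the
diagnostic statistics (likelihood ratios, their confidence intervals and
post-test probabilities) and the confusion-matrix reconstruction from
published per-class statistics are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

from .textmodel import Mention

__all__ = [
    "ConfusionMatrix2x2", "MetricReport", "match_spans", "attribute_metrics",
    "cohen_kappa", "reconstruct_confusion", "likelihood_ratios",
    "post_test_probability", "pairwise_agreement",
]


# ---------------------------------------------------------------------------
# confusion matrix and diagnostic statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total

    def precision_minority(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    def per_class_prf(self) -> dict[str, dict[str, float]]:
        """P/R/F for the minority (positive) and majority (negative) class."""
        out = {}
        for name, tp, fp, fn in (
            ("minority", self.tp, self.fp, self.fn),
            ("majority", self.tn, self.fn, self.fp),
        ):
            p = tp / (tp + fp) if tp + fp else float("nan")
            r = tp / (tp + fn) if tp + fn else float("nan")
            f = 2 * p * r / (p + r) if p + r else 0.0
            out[name] = {"precision": p, "recall": r, "f": f}
        return out

    def macro_f(self) -> float:
        pc = self.per_class_prf()
        return (pc["minority"]["f"] + pc["majority"]["f"]) / 2

    def kappa(self) -> float:
        a, b = np.zeros(self.total, dtype=int), np.zeros(self.total, dtype=int)
        a[: self.tp + self.fn] = 1                       # gold positives
        b[: self.tp] = 1                                 # predicted, agreeing
        b[self.tp + self.fn : self.tp + self.fn + self.fp] = 1
        return cohen_kappa(a.tolist(), b.tolist())


def reconstruct_confusion(
    n_total: int,
    n_gold_pos: int,
    n_flagged: int,
    precision_min: float,
    recall_min: float,
    tolerance: float = 0.005,
) -> ConfusionMatrix2x2:
    """Rebuild TP/FP/FN/TN from published per-class summary statistics.

    ``precision_min``/``recall_min`` are the printed (rounded) minority-class
    precision and recall.  The two implied TP counts,
    ``precision_min * n_flagged`` and ``recall_min * n_gold_pos``, must agree
    after rounding; otherwise the inputs are inconsistent.
    """
    tp_from_recall = round(recall_min * n_gold_pos)
    tp_from_precision = round(precision_min * n_flagged)
    if tp_from_recall != tp_from_precision:
        # allow printed-rounding slack: accept if either implied TP round-trips
        candidates = {tp_from_recall, tp_from_precision}
        ok = [
            tp for tp in candidates
            if abs(tp / n_flagged - precision_min) <= tolerance + 0.5 / n_flagged
            and abs(tp / n_gold_pos - recall_min) <= tolerance + 0.5 / n_gold_pos
        ]
        if not ok:
            raise ValueError(
                "inconsistent inputs: precision implies TP="
                f"{tp_from_precision}, recall implies TP={tp_from_recall}"
            )
        tp_from_recall = min(ok)
    tp = tp_from_recall
    fp = n_flagged - tp
    fn = n_gold_pos - tp
    tn = n_total - tp - fp - fn
    return ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class LikelihoodRatios:
    lr_pos: float
    lr_neg: float
    ci_pos: tuple[float, float]
    ci_neg: tuple[float, float]
    infinite_lr_pos: bool = False
    undefined_ci: bool = False


def likelihood_ratios(cm: ConfusionMatrix2x2, confidence: float = 0.95) -> LikelihoodRatios:
    """LR+ = sens/(1-spec), LR- = (1-sens)/spec, CIs by the log method.

    A specificity of 1 (no false positives) gives an infinite LR+, returned
    as ``inf`` with ``infinite_lr_pos`` set — perfect prediction on a small
    sample rather than a real effect.
    """
    if cm.tp + cm.fn == 0 or cm.fp + cm.tn == 0:
        raise ValueError("both gold classes must be non-empty")
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2)
    sens, spec = cm.sensitivity, cm.specificity
    nan_ci = (float("nan"), float("nan"))

    if spec == 1.0:
        lr_pos, ci_pos, inf_pos = float("inf"), nan_ci, True
    else:
        lr_pos = sens / (1 - spec)
        if cm.tp == 0 or cm.fp == 0:
            ci_pos = nan_ci
        else:
            se = math.sqrt(1 / cm.tp - 1 / (cm.tp + cm.fn)
                           + 1 / cm.fp - 1 / (cm.fp + cm.tn))
            ci_pos = (lr_pos * math.exp(-z * se), lr_pos * math.exp(z * se))
        inf_pos = False

    lr_neg = (1 - sens) / spec if spec > 0 else float("inf")
    if cm.fn == 0 or cm.tn == 0 or spec == 0:
        ci_neg = nan_ci
    else:
        se = math.sqrt(1 / cm.fn - 1 / (cm.tp + cm.fn)
                       + 1 / cm.tn - 1 / (cm.fp + cm.tn))
        ci_neg = (lr_neg * math.exp(-z * se), lr_neg * math.exp(z * se))

    undefined = any(math.isnan(x) for x in (*ci_pos, *ci_neg))
    return LikelihoodRatios(lr_pos, lr_neg, ci_pos, ci_neg, inf_pos, undefined)


def post_test_probability(pretest_prevalence: float, lr: float) -> float:
    """Convert a pre-test probability through a likelihood ratio."""
    if not 0 < pretest_prevalence < 1:
        raise ValueError("pretest_prevalence must be in (0, 1)")
    if lr < 0:
        raise ValueError("likelihood ratio must be non-negative")
    if math.isinf(lr):
        return 1.0
    odds = pretest_prevalence / (1 - pretest_prevalence) * lr
    return odds / (1 + odds)


# ---------------------------------------------------------------------------
# span matching
# ---------------------------------------------------------------------------


def match_spans(
    gold: list[Mention],
    pred: list[Mention],
    mode: str = "exact",
) -> tuple[list[tuple[Mention, Mention]], ConfusionMatrix2x2]:
    """One-to-one pairing of gold and predicted mention spans.

    ``exact`` requires identical character spans; ``overlap`` requires at
    least one shared character, pairing greedily left-to-right with a
    longest-overlap tie-break.  Unmatched gold spans count FN, unmatched
    predictions FP (TN is structurally 0 at span level).
    """
    if mode not in {"exact", "overlap"}:
        raise ValueError("mode must be 'exact' or 'overlap'")
    pairs: list[tuple[Mention, Mention]] = []
    used: set[int] = set()
    for g in sorted(gold, key=lambda m: (m.char_start, m.char_end)):
        best_j, best_ov = None, 0
        for j, p in enumerate(pred):
            if j in used:
                continue
            if mode == "exact":
                if (g.char_start, g.char_end) == (p.char_start, p.char_end):
                    best_j = j
                    break
            else:
                ov = min(g.char_end, p.char_end) - max(g.char_start, p.char_start)
                if ov > 0 and ov > best_ov:
                    best_j, best_ov = j, ov
        if best_j is not None:
            used.add(best_j)
            pairs.append((g, pred[best_j]))
    cm = ConfusionMatrix2x2(
        tp=len(pairs), fp=len(pred) - len(pairs), fn=len(gold) - len(pairs), tn=0
    )
    return pairs, cm


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    per_class: dict[str, dict[str, float]]
    micro_precision: float
    micro_recall: float
    micro_f: float
    macro_precision: float
    macro_recall: float
    macro_f: float
    kappa: float
    n_items: int
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "micro": {"precision": self.micro_precision, "recall": self.micro_recall,
                      "f": self.micro_f},
            "macro": {"precision": self.macro_precision, "recall": self.macro_recall,
                      "f": self.macro_f},
            "kappa": self.kappa,
            "n_items": self.n_items,
            "flags": self.flags,
        }


def cohen_kappa(labels_a: list, labels_b: list) -> float:
    """Cohen's kappa; 1.0 when both raters agree perfectly, even if the
    chance-expected agreement is also 1 (single realised class)."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    if len(labels_a) == 0:
        raise ValueError("label vectors must be non-empty")
    if labels_a == labels_b and len(set(labels_a)) == 1:
        return 1.0
    return float(cohen_kappa_score(labels_a, labels_b))


def classification_report(gold_labels: list, pred_labels: list) -> MetricReport:
    """Micro/macro P/R/F + kappa over aligned label vectors."""
    if len(gold_labels) != len(pred_labels):
        raise ValueError("label vectors must have equal length")
    n = len(gold_labels)
    if n == 0:
        return MetricReport({}, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0,
                            flags=["empty"])
    classes = sorted(set(gold_labels) | set(pred_labels))
    gold_classes = sorted(set(gold_labels))
    p, r, f, _ = precision_recall_fscore_support(
        gold_labels, pred_labels, labels=classes, average=None, zero_division=np.nan
    )
    per_class = {
        c: {"precision": float(p[i]), "recall": float(r[i]), "f": float(f[i])}
        for i, c in enumerate(classes)
    }
    flags = [f"undefined_precision:{c}" for c in classes
             if math.isnan(per_class[c]["precision"])]
    # micro: pool one-vs-rest counts over classes (= accuracy for single label)
    acc = sum(a == b for a, b in zip(gold_labels, pred_labels)) / n
    # macro: unweighted mean over classes present in gold; classes with no
    # defined value (e.g. precision with zero predictions) are skipped
    gp = [per_class[c] for c in gold_classes]

    def _nanmean(vals: list[float]) -> float:
        kept = [v for v in vals if not math.isnan(v)]
        return float(np.mean(kept)) if kept else float("nan")

    macro_p = _nanmean([d["precision"] for d in gp])
    macro_r = _nanmean([d["recall"] for d in gp])
    macro_f = _nanmean([d["f"] for d in gp])
    return MetricReport(per_class, acc, acc, acc, macro_p, macro_r, macro_f,
                        cohen_kappa(list(gold_labels), list(pred_labels)), n, flags)


def attribute_metrics(
    pairs: list[tuple[Mention, Mention]], attribute: str
) -> MetricReport:
    """Metrics for one attribute over matched span pairs."""
    if attribute not in {"status", "temporality", "polarity"}:
        raise AttributeError(f"unknown mention attribute {attribute!r}")
    gold = [getattr(g, attribute) for g, _ in pairs]
    pred = [getattr(p, attribute) for _, p in pairs]
    return classification_report(gold, pred)


def span_metrics(cm: ConfusionMatrix2x2) -> dict[str, float]:
    """Precision/recall/F from span-level TP/FP/FN counts."""
    if cm.tp + cm.fp + cm.fn == 0:
        return {"precision": 1.0, "recall": 1.0, "f": 1.0}
    p = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else float("nan")
    r = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else float("nan")
    f = 2 * p * r / (p + r) if p + r else 0.0
    return {"precision": p, "recall": r, "f": f}


def pairwise_agreement(label_sets: dict[str, list]) -> MetricReport:
    """Micro-averaged pairwise agreement between >2 annotators.

    Each annotator pair contributes its aligned labels to one pooled
    comparison (first annotator of the pair plays "gold").
    """
    names = sorted(label_sets)
    if len(names) < 2:
        raise ValueError("need at least two annotators")
    gold_pool: list = []
    pred_pool: list = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(label_sets[a]) != len(label_sets[b]):
                raise ValueError("annotator label vectors must align")
            gold_pool.extend(label_sets[a])
            pred_pool.extend(label_sets[b])
    return classification_report(gold_pool, pred_pool)
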