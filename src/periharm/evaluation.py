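"""Corpus-level evaluation: mention-level span/attribute scoring against a
gold standard, and service-user-level diagnostic statistics.

Gold and predicted annotations travel as standoff tables with columns
``doc_id, char_start, char_end, status, temporality, polarity`` (0-based
half-open offsets).  Span pairing happens per document; attribute metrics
pool the matched pairs over the whole corpus.
"""

from __future__ import annotations

import math

import pandas as pd

from .aggregate import ServiceUserSummary
from .metrics import (ConfusionMatrix2x2, attribute_metrics, likelihood_ratios,
                      match_spans, post_test_probability, span_metrics)
from .textmodel import AnnotatedDocument, Mention

STANDOFF_COLUMNS = ["doc_id", "char_start", "char_end",
                    "status", "temporality", "polarity"]

__all__ = ["standoff_from_docs", "mentions_by_doc", "evaluate_mention_level",
            "evaluate_user_level", "STANDOFF_COLUMNS"]


def standoff_from_docs(docs: list[AnnotatedDocument]) -> pd.DataFrame:
    rows = [
        {"doc_id": d.doc_id, "char_start": m.char_start, "char_end": m.char_end,
         "status": m.status, "temporality": m.temporality, "polarity": m.polarity}
        for d in docs for m in d.mentions
    ]
    return pd.DataFrame(rows, columns=STANDOFF_COLUMNS)


def mentions_by_doc(standoff: pd.DataFrame) -> dict[str, list[Mention]]:
    missing = set(STANDOFF_COLUMNS) - set(standoff.columns)
    if missing:
        raise ValueError(f"standoff table missing columns: {', '.join(sorted(missing))}")
    out: dict[str, list[Mention]] = {}
    for row in standoff.itertuples():
        out.setdefault(str(row.doc_id), []).append(Mention(
            start=0, end=0,
            char_start=int(row.char_start), char_end=int(row.char_end),
            status=str(row.status), temporality=str(row.temporality),
            polarity=str(row.polarity),
        ))
    return out


def evaluate_mention_level(
    gold: pd.DataFrame, pred: pd.DataFrame, mode: str = "exact"
) -> dict:
    """Span P/R/F plus per-attribute reports pooled over matched pairs."""
    gold_by, pred_by = mentions_by_doc(gold), mentions_by_doc(pred)
    tp = fp = fn = 0
    pairs = []
    for doc_id in sorted(set(gold_by) | set(pred_by)):
        p, cm = match_spans(gold_by.get(doc_id, []), pred_by.get(doc_id, []), mode)
        pairs.extend(p)
        tp, fp, fn = tp + cm.tp, fp + cm.fp, fn + cm.fn
    span_cm = ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=0)
    out = {"mode": mode, "span": span_metrics(span_cm),
           "span_counts": {"tp": tp, "fp": fp, "fn": fn}}
    for attr in ("status", "temporality", "polarity"):
        out[attr] = attribute_metrics(pairs, attr).as_dict()
    return out


def evaluate_user_level(
    gold_flags: pd.DataFrame,
    summaries: list[ServiceUserSummary],
    use_heuristic: bool = True,
    gold_column: str = "flagged_plain",
) -> dict:
    """Diagnostic statistics for user flagging against gold per-user flags.

    ``gold_flags`` needs columns ``user_id`` and ``gold_column``.  Predicted
    flags come from the aggregation summaries (heuristic or plain).
    """
    pred = {s.user_id: (s.flagged_heuristic if use_heuristic else s.flagged_plain)
            for s in summaries}
    gold = dict(zip(gold_flags.user_id.astype(str), gold_flags[gold_column]))
    users = sorted(gold)
    tp = sum(gold[u] and pred.get(u, False) for u in users)
    fp = sum((not gold[u]) and pred.get(u, False) for u in users)
    fn = sum(gold[u] and not pred.get(u, False) for u in users)
    tn = sum((not gold[u]) and not pred.get(u, False) for u in users)
    cm = ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn)
    out: dict = {
        "n_users": cm.total,
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "flagged": tp + fp,
        "prevalence": cm.prevalence,
        "per_class": cm.per_class_prf(),
        "macro_f": cm.macro_f(),
        "kappa": cm.kappa(),
    }
    if 0 < tp + fn < cm.total:
        lr = likelihood_ratios(cm)
        out["lr_pos"], out["lr_neg"] = lr.lr_pos, lr.lr_neg
        out["lr_pos_ci"], out["lr_neg_ci"] = list(lr.ci_pos), list(lr.ci_neg)
        out["infinite_lr_pos"] = lr.infinite_lr_pos
        prev = cm.prevalence
        out["post_test_pos"] = post_test_probability(prev, lr.lr_pos)
        out["post_test_neg"] = post_test_probability(prev, lr.lr_neg)
        if not lr.infinite_lr_pos and not any(math.isnan(x) for x in lr.ci_pos):
            out["post_test_pos_ci"] = [post_test_probability(prev, x) for x in lr.ci_pos]
        if not any(math.isnan(x) for x in lr.ci_neg):
            out["post_test_neg_ci"] = [post_test_probability(prev, x) for x in lr.ci_neg]
    return out
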