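"""Service-user-level aggregation.

A "true" mention asserts a current act by the patient: status = relevant,
polarity = positive, temporality = current.  A user is plainly flagged by >=1
true mention across all their notes; the selection heuristic flags only users
with >=k true mentions (k = 2 by default), trading recall for precision on
the grounds that a real self-harm event is documented repeatedly at
follow-up.  Duplicate documentation of one event is deliberately not
deduplicated for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .textmodel import AnnotatedDocument, Mention

__all__ = ["is_true_mention", "aggregate_users", "ServiceUserSummary", "summary_table"]


def is_true_mention(m: Mention) -> bool:
    return (m.status == "relevant" and m.polarity == "positive"
            and m.temporality == "current")


@dataclass(frozen=True)
class ServiceUserSummary:
    user_id: str
    n_documents: int
    n_mentions_total: int
    n_true_mentions: int
    flagged_plain: bool
    flagged_heuristic: bool


def aggregate_users(
    docs: list[AnnotatedDocument],
    k: int = 2,
    distinct_documents: bool = False,
) -> list[ServiceUserSummary]:
    """One summary per distinct user, counts pooled over all their notes.

    With ``distinct_documents`` the heuristic counts at most one true mention
    per note (variant; the default pools every mention).
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    by_user: dict[str, list[AnnotatedDocument]] = {}
    for d in docs:
        by_user.setdefault(d.user_id, []).append(d)
    out = []
    for user_id in sorted(by_user):
        user_docs = by_user[user_id]
        n_total = sum(len(d.mentions) for d in user_docs)
        n_true = sum(sum(is_true_mention(m) for m in d.mentions) for d in user_docs)
        if distinct_documents:
            n_for_k = sum(any(is_true_mention(m) for m in d.mentions) for d in user_docs)
        else:
            n_for_k = n_true
        out.append(ServiceUserSummary(
            user_id=user_id,
            n_documents=len(user_docs),
            n_mentions_total=n_total,
            n_true_mentions=n_true,
            flagged_plain=n_true >= 1,
            flagged_heuristic=n_for_k >= k,
        ))
    return out


def summary_table(summaries: list[ServiceUserSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries],
                        columns=["user_id", "n_documents", "n_mentions_total",
                                 "n_true_mentions", "flagged_plain",
                                 "flagged_heuristic"])
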