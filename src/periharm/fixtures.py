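"""Synthetic pseudo-EHR generation and the worked-example regression bank.

Real psychiatric EHRs cannot be redistributed, so every pipeline stage is
exercised against (a) a frozen bank of short worked examples covering each
linguistic phenomenon the rules handle, and (b) a seeded generator that
assembles plausible progress notes from neutral filler plus phenomenon
templates, emitting gold annotations by construction.

The generator emulates the shape of a perinatal mental-health caseload at
desk scale: a user-level "case" probability of 0.19 mirrors the reference
prevalence of users with a true self-harm mention, and case users receive a
true mention in most of their notes, so the majority of cases carry more
than one mention — the property that motivates the >=2-mention selection
heuristic.  Templates use placeholder patients only ("She", "Ms A"); no real
identifiers ever appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WorkedExample", "worked_example_bank", "FixtureSpec", "GoldMention",
           "GoldCorpus", "generate_corpus"]


# ---------------------------------------------------------------------------
# worked-example bank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkedExample:
    """One carrier sentence and its expected annotation.

    ``span`` is the expected mention surface text, or None when the sentence
    must yield no mention at all.  Attribute fields left None are not
    asserted for that example.
    """

    text: str
    span: str | None
    status: str | None = None
    temporality: str | None = None
    polarity: str | None = None
    phenomenon: str = ""


def worked_example_bank() -> list[WorkedExample]:
    """The frozen regression surface: every phenomenon the rules implement."""
    W = WorkedExample
    return [
        # span construction
        W("she had scratches on her arm", "scratches", phenomenon="indicative-noun"),
        W("she had a self-harming impulse", "self-harming impulse", phenomenon="adj-noun"),
        W("she cut herself", "cut herself", "relevant", "current", "positive",
          phenomenon="verb-object"),
        W("she climbed out a window and fell off", "fell off", phenomenon="passive-fall"),
        # lexicon categories in their carrier sentences
        W("She took an overdose", "overdose", "relevant", "current", "positive",
          phenomenon="plain-act"),
        W("She had cut her left wrist", "cut her left wrist", "relevant",
          phenomenon="body-part"),
        W("She lacerated her arm", "lacerated her arm", "relevant",
          phenomenon="harm-action"),
        W("Her mother took an overdose", "overdose", "non-relevant",
          phenomenon="third-party"),
        W("She would cut herself", "cut herself", "non-relevant",
          phenomenon="modal"),
        W("She cut herself deliberately", "cut herself", "relevant", "current",
          "positive", phenomenon="intent"),
        W("She took 12 paracetamol tablets", "took 12 paracetamol tablets",
          phenomenon="medication"),
        W("Possibility of self-harm", "self-harm", "non-relevant",
          phenomenon="modality"),
        W("Denies self-harm", "self-harm", polarity="negative", phenomenon="negation"),
        W("She disclosed having thoughts of cutting herself", "cutting herself",
          "non-relevant", phenomenon="reported-ideation"),
        W("She started self-harming in her teens", "self-harming",
          temporality="historical", phenomenon="life-stage"),
        W("Previous episodes of self-harm", "self-harm", temporality="historical",
          phenomenon="past-reference"),
        W("Current episode of self-harm", "self-harm", temporality="current",
          phenomenon="present-reference"),
        # dependency negation rules
        W("she did not cut herself", "cut herself", polarity="negative",
          phenomenon="neg-dependency"),
        W("she did not report harming herself", "harming herself",
          polarity="negative", phenomenon="negated-report"),
        W("she denies any self-harm", "self-harm", polarity="negative",
          phenomenon="negation-governor"),
        W("Suicide attempts: X", "Suicide attempts", polarity="negative",
          phenomenon="symbol-negation"),
        # temporality
        W("took an overdose ten years ago", "overdose", temporality="historical",
          phenomenon="years-ago"),
        W("chronic history of self-harm", "self-harm", temporality="current",
          phenomenon="chronic"),
        W("she took an overdose last night", "overdose", "relevant", "current",
          "positive", phenomenon="recent"),
        W("no current or past suicide attempts", "suicide attempts",
          temporality="historical", polarity="negative",
          phenomenon="coordinated-temporality"),
        # error-analysis traps
        W("Sertraline 50mg OD AM", None, phenomenon="dosage-od"),
        W("tends to jump to conclusions", None, phenomenon="jump-idiom"),
        W("She jumped down the stairs", None, phenomenon="jump-stairs"),
        W("threatened to jump through a window", "jump through a window",
          phenomenon="jump-valid"),
        W("no history of suicide", "suicide", polarity="negative",
          phenomenon="suicide-history"),
        W("2 x OD", "OD", phenomenon="shorthand"),
    ]


# ---------------------------------------------------------------------------
# synthetic corpus generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Controls for the synthetic corpus.

    ``class_mix`` gives proportions over the seven phenomenon classes; the
    true-mention classes (plain-act, shorthand) are sampled for case users'
    true notes, the remainder for confound sentences.  ``p_case`` is the
    probability a user is a genuine case (reference-standard prevalence),
    ``p_true_mention`` the per-note probability that a case user's note
    documents the act, and ``p_confound`` the per-note probability of a
    non-true phenomenon sentence for any user.
    """

    n_users: int = 50
    notes_per_user: tuple[int, int] = (1, 6)
    p_true_mention: float = 0.7
    p_case: float = 0.19
    p_confound: float = 0.35
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "plain-act": 0.25, "negated": 0.15, "hedged": 0.20, "historical": 0.15,
        "third-party": 0.10, "shorthand": 0.05, "exclusion-trap": 0.10,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        for p in (self.p_true_mention, self.p_case, self.p_confound):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_users < 1 or self.notes_per_user[0] < 1 \
                or self.notes_per_user[1] < self.notes_per_user[0]:
            raise ValueError("invalid corpus dimensions")


@dataclass(frozen=True)
class GoldMention:
    doc_id: str
    char_start: int
    char_end: int
    status: str
    temporality: str
    polarity: str

    @property
    def is_true(self) -> bool:
        return (self.status, self.temporality, self.polarity) == \
            ("relevant", "current", "positive")


@dataclass
class GoldCorpus:
    documents: pd.DataFrame           # doc_id, user_id, text
    mentions: list[GoldMention]
    heuristic_k: int = 2

    def user_flags(self) -> pd.DataFrame:
        """Per-user gold flags recomputed from the gold mentions."""
        doc_user = dict(zip(self.documents.doc_id, self.documents.user_id))
        counts: dict[str, int] = {u: 0 for u in self.documents.user_id}
        for m in self.mentions:
            if m.is_true:
                counts[doc_user[m.doc_id]] += 1
        return pd.DataFrame({
            "user_id": sorted(counts),
            "n_true_mentions": [counts[u] for u in sorted(counts)],
            "flagged_plain": [counts[u] >= 1 for u in sorted(counts)],
            "flagged_heuristic": [counts[u] >= self.heuristic_k for u in sorted(counts)],
        })


# phenomenon templates: (text, span substring or None, status, temporality, polarity)
_TEMPLATES: dict[str, list[tuple[str, str | None, str, str, str]]] = {
    "plain-act": [
        ("She took an overdose last night.", "overdose", "relevant", "current", "positive"),
        ("She cut herself deliberately.", "cut herself", "relevant", "current", "positive"),
        ("She lacerated her arm.", "lacerated her arm", "relevant", "current", "positive"),
        ("She had cut her left wrist.", "cut her left wrist", "relevant", "current", "positive"),
        ("She took 12 paracetamol tablets.", "took 12 paracetamol tablets",
         "relevant", "current", "positive"),
    ],
    "shorthand": [
        ("2 x OD.", "OD", "relevant", "current", "positive"),
        ("D/S/H this morning.", "D/S/H", "relevant", "current", "positive"),
    ],
    "negated": [
        ("She denies any self-harm.", "self-harm", "relevant", "current", "negative"),
        ("she did not cut herself.", "cut herself", "relevant", "current", "negative"),
        ("Suicide attempts: X.", "Suicide attempts", "relevant", "current", "negative"),
        ("no history of suicide.", "suicide", "relevant", "historical", "negative"),
    ],
    "hedged": [
        ("She disclosed having thoughts of cutting herself.", "cutting herself",
         "non-relevant", "current", "positive"),
        ("Possibility of self-harm.", "self-harm", "non-relevant", "current", "positive"),
        ("She would cut herself.", "cut herself", "non-relevant", "current", "positive"),
    ],
    "historical": [
        ("took an overdose ten years ago.", "overdose", "relevant", "historical", "positive"),
        ("Previous episodes of self-harm.", "self-harm", "relevant", "historical", "positive"),
        ("She started self-harming in her teens.", "self-harming",
         "relevant", "historical", "positive"),
    ],
    "third-party": [
        ("Her mother took an overdose.", "overdose", "non-relevant", "current", "positive"),
        ("Her sister cut herself.", "cut herself", "non-relevant", "current", "positive"),
    ],
    "exclusion-trap": [
        ("Sertraline 50mg OD AM.", None, "", "", ""),
        ("tends to jump to conclusions.", None, "", "", ""),
        ("Paracetamol 500mg OD.", None, "", "", ""),
    ],
}

_TRUE_CLASSES = ("plain-act", "shorthand")

_FILLERS = [
    "Attended the appointment with the care coordinator.",
    "Sleep and appetite remain stable.",
    "Engaging well with the team.",
    "Seen at home with the baby.",
    "Discussed feeding and support at the visit.",
    "Settled in mood during the review.",
]


def generate_corpus(spec: FixtureSpec, heuristic_k: int = 2) -> GoldCorpus:
    """Deterministic (seeded) corpus of pseudo-notes plus gold annotations."""
    rng = np.random.default_rng(spec.seed)
    mix_true = _renormalise(spec.class_mix, _TRUE_CLASSES)
    confound_classes = tuple(c for c in spec.class_mix if c not in _TRUE_CLASSES)
    mix_conf = _renormalise(spec.class_mix, confound_classes)

    rows = []
    gold: list[GoldMention] = []
    for u in range(spec.n_users):
        user_id = f"u{u:04d}"
        is_case = rng.random() < spec.p_case
        lo, hi = spec.notes_per_user
        n_notes = int(rng.integers(lo, hi + 1))
        for d in range(n_notes):
            doc_id = f"{user_id}-n{d:02d}"
            sentences = [str(rng.choice(_FILLERS))]
            phenomenon: tuple | None = None
            if is_case and mix_true and rng.random() < spec.p_true_mention:
                cls = _sample(rng, mix_true)
                phenomenon = _TEMPLATES[cls][int(rng.integers(len(_TEMPLATES[cls])))]
            elif mix_conf and rng.random() < spec.p_confound:
                cls = _sample(rng, mix_conf)
                phenomenon = _TEMPLATES[cls][int(rng.integers(len(_TEMPLATES[cls])))]
            insert_at = 1
            if phenomenon is not None:
                sentences.insert(insert_at, phenomenon[0])
            sentences.append(str(rng.choice(_FILLERS)))
            text = "\n".join(sentences)
            if phenomenon is not None and phenomenon[1] is not None:
                sent_off = text.index(phenomenon[0])
                span_off = sent_off + phenomenon[0].index(phenomenon[1])
                gold.append(GoldMention(
                    doc_id=doc_id,
                    char_start=span_off,
                    char_end=span_off + len(phenomenon[1]),
                    status=phenomenon[2],
                    temporality=phenomenon[3],
                    polarity=phenomenon[4],
                ))
            rows.append({"doc_id": doc_id, "user_id": user_id, "text": text})
    documents = pd.DataFrame(rows, columns=["doc_id", "user_id", "text"])
    return GoldCorpus(documents=documents, mentions=gold, heuristic_k=heuristic_k)


def _renormalise(mix: dict[str, float], keep: tuple[str, ...]) -> dict[str, float]:
    # a degenerate mix (e.g. 100% negated) may leave no mass in a group, in
    # which case that group simply generates nothing
    sub = {c: mix[c] for c in keep if mix.get(c, 0) > 0}
    z = sum(sub.values())
    return {c: v / z for c, v in sub.items()} if sub else {}


def _sample(rng: np.random.Generator, mix: dict[str, float]) -> str:
    names = sorted(mix)
    return str(rng.choice(names, p=[mix[n] for n in names]))
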