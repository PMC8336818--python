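"""Layer 2: semantic tagging of tokens against 13 manually curated lexicons.

Categories cover self-harm synonyms (SH), harm actions, body parts, family
members, hedging/ideation markers, intent, medication names, modality,
negation, reported speech, life stages, and past/present temporal references.
The shipped term lists are a reconstruction seeded from the published category
examples and are extendable by pointing ``load_lexicons`` at another
directory.

Matching is case-insensitive, on lemma first with surface as fallback, so an
entry ``deny`` tags ``Denies`` and ``suicide attempt`` tags ``suicide
attempts``.  Multi-word terms are matched as token sequences; for each span
the longest match wins, and ties between categories yield one tag per
category on the same span.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .textmodel import AnnotatedDocument, SemanticTag, _data_path

CATEGORIES = (
    "SH", "BODY_PART", "HARM_ACTION", "FAMILY", "HEDGING", "INTENT", "MED",
    "MODALITY", "NEGATION", "R_SPEECH", "LIFE_STAGE", "PAST", "PRESENT",
)


class LexiconError(ValueError):
    """Raised when the lexicon directory is malformed or incomplete."""


@dataclass
class LexiconSet:
    """The 13 term lists, keyed by category; terms are lower-cased word tuples."""

    categories: dict[str, list[tuple[str, ...]]]

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.categories]
        if missing:
            raise LexiconError(f"missing lexicon categories: {', '.join(missing)}")
        for cat, terms in self.categories.items():
            if not terms:
                raise LexiconError(f"lexicon category {cat} is empty")
            if len(set(terms)) != len(terms):
                raise LexiconError(f"duplicate terms in lexicon category {cat}")

    def terms(self, category: str) -> list[str]:
        return [" ".join(t) for t in self.categories[category]]

    @property
    def max_term_length(self) -> int:
        return max(len(t) for ts in self.categories.values() for t in ts)


def load_lexicons(directory: str | Path | None = None) -> LexiconSet:
    """Load ``<CATEGORY>.txt`` files (one term per line, ``#`` comments)."""
    d = Path(directory) if directory is not None else _data_path("lexicons")
    cats: dict[str, list[tuple[str, ...]]] = {}
    for cat in CATEGORIES:
        f = d / f"{cat}.txt"
        if not f.exists():
            raise LexiconError(f"missing lexicon file for category {cat}: {f}")
        terms: list[tuple[str, ...]] = []
        for line in f.read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip().lower()
            if line:
                t = tuple(line.split())
                if t not in terms:
                    terms.append(t)
        cats[cat] = terms
    return LexiconSet(cats)


def _token_matches(tok, word: str) -> bool:
    return tok.lemma == word or tok.lower == word


def tag_semantics(doc: AnnotatedDocument, lexicons: LexiconSet) -> AnnotatedDocument:
    """Assign semantic tags in place (idempotent); returns the document."""
    max_len = lexicons.max_term_length
    tags: set[SemanticTag] = set()
    n = len(doc.tokens)
    for i in range(n):
        # longest match starting at i, per category
        best_len: dict[str, int] = {}
        for cat, terms in lexicons.categories.items():
            for term in terms:
                L = len(term)
                if L > n - i or L <= best_len.get(cat, 0):
                    continue
                if all(_token_matches(doc.tokens[i + k], term[k]) for k in range(L)):
                    best_len[cat] = L
        if not best_len:
            continue
        overall = max(best_len.values())
        for cat, L in best_len.items():
            if L == overall:
                tags.add(SemanticTag(i, i + L, cat))
    # drop matches nested inside a longer match of the same category
    kept = [
        t for t in tags
        if not any(
            u.category == t.category and (u.start, u.end) != (t.start, t.end)
            and u.start <= t.start and t.end <= u.end
            for u in tags
        )
    ]
    doc.semantic_tags = sorted(kept, key=lambda t: (t.start, t.end, t.category))
    return doc
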