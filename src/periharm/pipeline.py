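"""End-to-end pipeline: five processing layers applied in sequence.

1. linguistic preprocessing (tokens, POS, lemmas, dependencies)
2. lexical semantic tagging against the 13 lexicons
3. token-sequence grammar: mention spans, exclusions, history sections
4. dependency-based negation (polarity)
5. windowed contextual search (status, temporality)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .attributes import resolve_attributes
from .config import PipelineConfig
from .grammar import RulePattern, load_rules
from .lexicons import LexiconSet, load_lexicons, tag_semantics
from .mentions import (apply_exclusions, detect_history_sections,
                       detect_mentions, load_history_headers)
from .textmodel import AnnotatedDocument, load_token_exceptions, preprocess


@dataclass
class Pipeline:
    """A configured annotator; call :meth:`annotate` per note."""

    config: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        c = self.config
        self.exceptions = load_token_exceptions(c.exceptions_file)
        self.lexicons: LexiconSet = load_lexicons(c.lexicon_dir)
        self.rules: list[RulePattern] = load_rules(c.rules_file)
        self.headers = load_history_headers(c.headers_file)

    def annotate(self, text: str, user_id: str = "", doc_id: str = "") -> AnnotatedDocument:
        doc = preprocess(text, user_id=user_id, doc_id=doc_id,
                         exceptions=self.exceptions)
        tag_semantics(doc, self.lexicons)
        detect_mentions(doc, self.rules)
        apply_exclusions(doc, self.rules)
        detect_history_sections(doc, self.headers)
        resolve_attributes(doc, self.config)
        return doc

    def annotate_corpus(self, corpus: pd.DataFrame) -> list[AnnotatedDocument]:
        """Annotate a corpus table with columns doc_id, user_id, text."""
        required = {"doc_id", "user_id", "text"}
        missing = required - set(corpus.columns)
        if missing:
            raise ValueError(f"corpus table missing columns: {', '.join(sorted(missing))}")
        return [
            self.annotate(str(row.text), user_id=str(row.user_id), doc_id=str(row.doc_id))
            for row in corpus.itertuples()
        ]


def mention_table(docs: list[AnnotatedDocument]) -> pd.DataFrame:
    """Flat mention-level table (one row per detected mention)."""
    rows = []
    for doc in docs:
        for m in doc.mentions:
            rows.append({
                "doc_id": doc.doc_id,
                "user_id": doc.user_id,
                "char_start": m.char_start,
                "char_end": m.char_end,
                "text": doc.text[m.char_start : m.char_end],
                "status": m.status,
                "temporality": m.temporality,
                "polarity": m.polarity,
                "rules": "|".join(m.rule_provenance),
            })
    return pd.DataFrame(rows, columns=["doc_id", "user_id", "char_start", "char_end",
                                       "text", "status", "temporality", "polarity",
                                       "rules"])
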