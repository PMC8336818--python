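"""Layers 4-5: attribute resolution for detected mentions.

Polarity comes from the dependency tree (negation detection); status and
temporality come from a windowed contextual search over semantic tags, with a
history-section override for temporality.  Each resolver reads only the
output of layers 1-3, so the three attributes can be resolved in any order.

Polarity is negative when any of four conditions holds:

a. a mention token heads a ``neg`` dependency ("she did not cut herself");
b. the mention's governor is a reported-speech verb that is itself negated
   ("she did not report harming herself");
c. the mention is governed by a NEGATION-tagged word ("she denies any
   self-harm"), including a negative determiner on the mention's noun-phrase
   chain ("no history of suicide");
d. symbol negation: the mention is followed, after a colon on the same line,
   by a negation symbol ("Suicide attempts: X").

Status is demoted to non-relevant by hedging/ideation or modality cues in the
±w token window (w = 10 by default) and by third-party (family) linkage.  A
modality cue *after* the mention only demotes when its verb actually takes
the mention as a complement, unless ``paper_faithful_mode`` is set, in which
case any trailing modal in the window demotes — the stricter scoping repairs
a documented failure mode on sentences like "she thought the self-harm would
kill her".

Temporality defaults to current; PAST or life-stage cues in the window, or an
enclosing history section, make it historical.  "chronic" references stay
current, and when both PAST and PRESENT cues occur the cue nearest the
mention wins (ties go to current), except that coordinated temporal
modifiers with a PAST conjunct ("no current or past suicide attempts") are
historical.
"""

from __future__ import annotations

from .config import PipelineConfig
from .textmodel import AnnotatedDocument, Mention, Token, token_window

NEG_SYMBOLS = {"x", "✗", "×", "0", "nil", "none", "neg", "denied"}

__all__ = ["resolve_polarity", "resolve_status", "resolve_temporality",
           "resolve_attributes"]


def _anchor(doc: AnnotatedDocument, m: Mention) -> Token:
    """The mention token whose head lies outside the span (its syntactic root)."""
    for t in doc.tokens[m.start : m.end]:
        if t.head_index == t.index or not (m.start <= t.head_index < m.end):
            return t
    return doc.tokens[m.start]


def _governor(doc: AnnotatedDocument, m: Mention) -> Token | None:
    a = _anchor(doc, m)
    if a.head_index == a.index:
        return None
    return doc.tokens[a.head_index]


def _heads_neg(doc: AnnotatedDocument, index: int) -> bool:
    return any(t.dep_label == "neg" and t.head_index == index and t.index != index
               for t in doc.tokens)


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------


def resolve_polarity(m: Mention, doc: AnnotatedDocument,
                     config: PipelineConfig | None = None) -> str:
    # (a) a mention token heads a 'neg' dependency
    for i in range(m.start, m.end):
        if _heads_neg(doc, i):
            return "negative"

    gov = _governor(doc, m)
    if gov is not None:
        gov_tags = doc.tags_at(gov.index)
        # (b) negated reported-speech governor
        if "R_SPEECH" in gov_tags and _heads_neg(doc, gov.index):
            return "negative"
        # (c) direct NEGATION governor
        if "NEGATION" in gov_tags:
            return "negative"

    # (c) continued: NEGATION determiner/modifier on the mention's NP chain
    if _np_chain_negated(doc, m):
        return "negative"

    # (d) symbol negation after a colon, same line
    if _symbol_negated(doc, m):
        return "negative"
    return "positive"


def _np_chain_negated(doc: AnnotatedDocument, m: Mention) -> bool:
    """Walk governors up through noun/preposition nodes looking for negation."""
    chain = [doc.tokens[i] for i in range(m.start, m.end)]
    cur = _anchor(doc, m)
    for _ in range(len(doc.tokens)):
        if cur.head_index == cur.index:
            break
        nxt = doc.tokens[cur.head_index]
        if nxt.pos not in {"NOUN", "ADP", "PRON"}:
            break
        chain.append(nxt)
        cur = nxt
    chain_idx = {t.index for t in chain}
    for t in doc.tokens:
        if t.head_index in chain_idx and t.index not in chain_idx:
            if t.dep_label in {"det", "neg", "amod"} and "NEGATION" in doc.tags_at(t.index):
                return True
    return False


def _symbol_negated(doc: AnnotatedDocument, m: Mention) -> bool:
    i = m.end
    toks = doc.tokens
    if i < len(toks) and toks[i].surface == ":":
        j = i + 1
        if j < len(toks) and toks[j].sentence_id == toks[i].sentence_id \
                and toks[j].lower in NEG_SYMBOLS:
            return True
    return False


# ---------------------------------------------------------------------------
# status
# ---------------------------------------------------------------------------


def resolve_status(m: Mention, doc: AnnotatedDocument,
                   config: PipelineConfig | None = None) -> str:
    config = config or PipelineConfig()
    window = token_window(doc, (m.start, m.end), config.window_width,
                          config.sentence_bounded_window)
    gov = _governor(doc, m)
    anchor = _anchor(doc, m)
    for t in window:
        tags = doc.tags_at(t.index)
        if "HEDGING" in tags:
            return "non-relevant"
        if "MODALITY" in tags:
            if t.index < m.start or config.paper_faithful_mode:
                return "non-relevant"
            # trailing modal: demote only when its verb takes the mention as
            # a complement, not when the mention is merely its subject
            modal_verb = t.head_index if t.pos in {"AUX", "PART"} else t.index
            if gov is not None and gov.index == modal_verb \
                    and anchor.dep_label in {"dobj", "pobj"}:
                return "non-relevant"
    if _family_linked(doc, m):
        return "non-relevant"
    return "relevant"


def _family_linked(doc: AnnotatedDocument, m: Mention) -> bool:
    """Third-party test: FAMILY token as clause subject or immediately left."""
    fam = [t for t in doc.tokens if "FAMILY" in doc.tags_at(t.index)]
    if not fam:
        return False
    sent = doc.tokens[m.start].sentence_id
    for t in fam:
        if t.sentence_id != sent:
            continue
        if 0 < m.start - t.index <= 3:
            return True
        gov = _governor(doc, m)
        verb = gov.index if gov is not None and gov.pos in {"VERB", "AUX"} \
            else _anchor(doc, m).index
        if t.dep_label == "nsubj" and t.head_index == verb:
            return True
        # possessive/subject family token heading the clause via a kin noun:
        # "her mother's overdose" -> mother governs the mention chain
        if t.index == _anchor(doc, m).head_index:
            return True
    return False


# ---------------------------------------------------------------------------
# temporality
# ---------------------------------------------------------------------------


def resolve_temporality(m: Mention, doc: AnnotatedDocument,
                        sections: list[tuple[int, int]] | None = None,
                        config: PipelineConfig | None = None) -> str:
    config = config or PipelineConfig()
    if sections is None:
        sections = doc.history_sections
    for s, e in sections:
        if s <= m.start and m.end <= e:
            return "historical"
    window = token_window(doc, (m.start, m.end), config.window_width,
                          config.sentence_bounded_window)
    # chronic/ongoing references are coded current
    if any(t.lemma == "chronic" or t.lower == "ongoing" for t in window):
        return "current"
    past = [t for t in window
            if doc.tags_at(t.index) & {"PAST", "LIFE_STAGE"}]
    present = [t for t in window if "PRESENT" in doc.tags_at(t.index)]
    if not past:
        return "current"
    if _coordinated_past(doc, past, present):
        return "historical"
    if not present:
        return "historical"

    def dist(t: Token) -> int:
        return m.start - t.index if t.index < m.start else t.index - (m.end - 1)

    d_past, d_present = min(map(dist, past)), min(map(dist, present))
    return "historical" if d_past < d_present else "current"


def _coordinated_past(doc: AnnotatedDocument, past: list[Token],
                      present: list[Token]) -> bool:
    """"current or past", "past and present": any PAST conjunct -> historical."""
    for p in past:
        for q in present:
            lo, hi = sorted((p.index, q.index))
            if hi - lo == 2 and doc.tokens[lo + 1].pos == "CCONJ":
                return True
    return False


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def resolve_attributes(doc: AnnotatedDocument,
                       config: PipelineConfig | None = None) -> AnnotatedDocument:
    """Resolve all three attributes for every mention (in place)."""
    config = config or PipelineConfig()
    for m in doc.mentions:
        m.polarity = resolve_polarity(m, doc, config)
        m.status = resolve_status(m, doc, config)
        m.temporality = resolve_temporality(m, doc, doc.history_sections, config)
    return doc
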