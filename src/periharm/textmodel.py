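"""Document/token data model and deterministic linguistic preprocessing.

This is the first processing layer of the pipeline: sentence detection,
tokenisation (with custom exceptions so that hyphenated self-harm terms and
clinical shorthand such as ``self-harm``, ``self-injury``, ``fh/o`` survive as
single tokens), coarse part-of-speech tagging, lemmatisation and a shallow
heuristic dependency annotation.

The dependency layer is a deterministic rule-based annotator, not a trained
parser.  It produces the relations the downstream layers consume: ``neg``
(negation particle attached to the verb it negates), ``nsubj``/``dobj``/``pobj``
argument links, ``det``/``amod`` noun-phrase structure, ``aux`` and ``xcomp``
verb chains.  On the short declarative sentences typical of psychiatric
progress notes these heuristics are reliable; they are not intended as a
general-purpose parser.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Token",
    "SemanticTag",
    "Mention",
    "AnnotatedDocument",
    "load_token_exceptions",
    "preprocess",
    "token_window",
]

# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class Token:
    """A single word token with its linguistic annotations.

    ``head_index`` is the document-level index of the syntactic governor;
    a root token is its own head.  Character offsets are 0-based half-open.
    """

    index: int
    surface: str
    lemma: str
    pos: str
    head_index: int
    dep_label: str
    sentence_id: int
    char_start: int
    char_end: int

    @property
    def lower(self) -> str:
        return self.surface.lower()


@dataclass(frozen=True)
class SemanticTag:
    """A lexicon category assigned to a contiguous token span.

    ``start``/``end`` are token indices, half-open.
    """

    start: int
    end: int
    category: str


@dataclass
class Mention:
    """A detected self-harm mention: a token span plus its three attributes.

    Defaults (``relevant``, ``current``, ``positive``) encode the pipeline's
    stance that an unqualified mention asserts a current act by the patient;
    attribute resolution only ever demotes from these defaults.
    """

    start: int
    end: int
    char_start: int
    char_end: int
    status: str = "relevant"
    temporality: str = "current"
    polarity: str = "positive"
    rule_provenance: list[str] = field(default_factory=list)

    def span_key(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AnnotatedDocument:
    doc_id: str
    user_id: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    semantic_tags: list[SemanticTag] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)
    history_sections: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_sentences(self) -> int:
        if not self.tokens:
            return 0
        return self.tokens[-1].sentence_id + 1

    def sentence_bounds(self, sentence_id: int) -> tuple[int, int]:
        """Token-index bounds (half-open) of a sentence."""
        idxs = [t.index for t in self.tokens if t.sentence_id == sentence_id]
        if not idxs:
            raise IndexError(f"no sentence {sentence_id}")
        return idxs[0], idxs[-1] + 1

    def tags_at(self, index: int) -> set[str]:
        """Semantic categories covering the token at ``index``."""
        return {t.category for t in self.semantic_tags if t.start <= index < t.end}

    def span_text(self, start: int, end: int) -> str:
        return self.text[self.tokens[start].char_start : self.tokens[end - 1].char_end]


# ---------------------------------------------------------------------------
# tokenisation
# ---------------------------------------------------------------------------

_DEFAULT_EXCEPTIONS_FILE = "token_exceptions.txt"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("periharm").joinpath("data", name)))


def load_token_exceptions(path: str | Path | None = None) -> list[str]:
    """Read the tokenisation-exception list: one term per line, ``#`` comments."""
    p = Path(path) if path is not None else _data_path(_DEFAULT_EXCEPTIONS_FILE)
    terms = []
    for line in p.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            terms.append(line.lower())
    return terms


def _build_token_regex(exceptions: Sequence[str]) -> re.Pattern:
    parts = []
    # longest first so e.g. "self-harming" beats "self-harm"
    for term in sorted(set(exceptions), key=len, reverse=True):
        parts.append(r"(?<![A-Za-z0-9])" + re.escape(term) + r"(?![A-Za-z0-9])")
    parts.append(r"\d+(?:\.\d+)?\s?(?:mg|mcg|g|ml|kg)\b")  # dose like "50mg"
    parts.append(r"\d+(?:\.\d+)?")
    parts.append(r"[A-Za-z]+(?:'[A-Za-z]+)?")
    parts.append(r"\S")  # any single non-space char (punctuation, symbols)
    return re.compile("|".join(parts), re.IGNORECASE)


def _raw_tokenise(text: str, exceptions: Sequence[str]) -> list[tuple[str, int, int]]:
    rx = _build_token_regex(exceptions)
    out = []
    for m in rx.finditer(text):
        surf = m.group(0)
        # split clitic negation: "didn't" -> "did" + "n't"
        if surf.lower().endswith("n't") and len(surf) > 3:
            out.append((surf[:-3], m.start(), m.end() - 3))
            out.append((surf[-3:], m.end() - 3, m.end()))
        else:
            out.append((surf, m.start(), m.end()))
    return out


_SENT_END = re.compile(r"[.!?]")


def _sentence_ids(
    raw: list[tuple[str, int, int]], text: str
) -> list[int]:
    """Assign sentence ordinals: boundaries after .!? and at blank-ish newlines."""
    ids = []
    sid = 0
    prev_end = 0
    for i, (surf, start, end) in enumerate(raw):
        if i > 0:
            gap = text[prev_end:start]
            if "\n" in gap:
                sid += 1
            elif _SENT_END.fullmatch(raw[i - 1][0]):
                sid += 1
        ids.append(sid)
        prev_end = end
    return ids


# ---------------------------------------------------------------------------
# part of speech
# ---------------------------------------------------------------------------

_DETS = {"the", "a", "an", "no", "any", "some", "each", "every", "this",
         "these", "those", "his", "their", "my", "your", "our", "its"}
_PRONS = {"she", "he", "it", "they", "i", "we", "you", "him", "them",
          "herself", "himself", "themselves", "myself", "who", "patient"}
_SUBJ_PRONS = {"she", "he", "they", "it", "i", "we", "you", "who", "patient"}
_ADPS = {"of", "on", "in", "at", "to", "off", "through", "down", "out", "with",
         "from", "into", "onto", "over", "under", "by", "via", "after",
         "before", "during", "up", "about", "for", "as", "since"}
_AUXES = {"did", "do", "does", "has", "have", "had", "was", "were", "is",
          "are", "am", "be", "been", "being", "will", "would", "could", "can",
          "may", "might", "shall", "should", "must"}
_CCONJS = {"and", "or", "but", "nor"}
_NEG_ADVS = {"not", "never", "n't"}
_ADJS = {"left", "right", "chronic", "current", "past", "previous", "recent",
         "historical", "young", "suicidal", "deliberate", "possible",
         "superficial", "old", "further", "present", "low", "high", "good",
         "settled", "pleasant", "poor"}

# base-form verbs the tagger recognises in clinical self-harm narratives
_VERBSET = {"cut", "burn", "hit", "lacerate", "jump", "fall", "climb", "take",
            "deny", "report", "say", "claim", "disclose", "harm", "kill",
            "start", "tend", "threaten", "mention", "swallow", "ingest",
            "slash", "stab", "strangle", "hang", "poison", "drink", "attend",
            "admit", "discharge", "sleep", "think", "try", "want", "feel",
            "state", "describe", "tell", "express", "overdose", "scratch",
            "present", "go", "come", "see", "appear", "seem", "remain",
            "require", "engage", "self-harm"}

_IRREGULAR_LEMMA = {
    "took": "take", "taken": "take", "taking": "take",
    "fell": "fall", "fallen": "fall",
    "felt": "feel", "thought": "think", "said": "say", "told": "tell",
    "had": "have", "has": "have", "did": "do", "does": "do",
    "was": "be", "were": "be", "is": "be", "are": "be", "been": "be",
    "am": "be", "being": "be",
    "drank": "drink", "drunk": "drink", "hung": "hang", "went": "go",
    "saw": "see", "came": "come", "children": "child", "women": "woman",
    "men": "man", "teeth": "tooth", "feet": "foot",
}

_WORD = re.compile(r"[A-Za-z]")
_NUMLIKE = re.compile(r"\d+(?:\.\d+)?(?:\s?(?:mg|mcg|g|ml|kg))?", re.IGNORECASE)


def _lemma(surface: str, pos: str) -> str:
    s = surface.lower()
    if pos in {"PUNCT", "NUM", "SYM"}:
        return s
    if s in _IRREGULAR_LEMMA:
        # "thought"/"felt" keep verb lemmas only when used as verbs; the
        # noun reading is handled by surface matching in the lexicon layer
        if s in {"thought", "felt"} and pos != "VERB":
            return s
        return _IRREGULAR_LEMMA[s]
    for suf in ("ies", "ied"):
        if s.endswith(suf) and len(s) > 4:
            return s[:-3] + "y"
    if s.endswith("es") and len(s) > 3 and (s[-4:-2] in {"ch", "sh", "ss"} or s[-3] in "xz"):
        return s[:-2]
    if s.endswith("s") and len(s) > 3 and not s.endswith("ss") and not s.endswith("us"):
        return s[:-1]
    for suf in ("ing", "ed"):
        if s.endswith(suf) and len(s) > len(suf) + 2:
            stem = s[: -len(suf)]
            if stem in _VERBSET:
                return stem
            if stem + "e" in _VERBSET:
                return stem + "e"
            if len(stem) > 2 and stem[-1] == stem[-2] and stem[:-1] in _VERBSET:
                return stem[:-1]
            # generic: undo consonant doubling, restore silent e conservatively
            if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "lsz":
                return stem[:-1]
            return stem
    return s


def _coarse_pos(raw: list[tuple[str, int, int]]) -> list[str]:
    n = len(raw)
    pos = ["X"] * n
    surfs = [s.lower() for s, _, _ in raw]
    # pass 1: closed classes and unambiguous shapes
    for i, s in enumerate(surfs):
        orig = raw[i][0]
        if not _WORD.search(orig) and not _NUMLIKE.fullmatch(orig):
            pos[i] = "SYM" if orig in {"✗", "×", "+"} else "PUNCT"
        elif _NUMLIKE.fullmatch(orig):
            pos[i] = "NUM"
        elif s in _NEG_ADVS:
            pos[i] = "ADV"
        elif s in _AUXES:
            pos[i] = "AUX"
        elif s in _DETS:
            pos[i] = "DET"
        elif s in _PRONS:
            pos[i] = "PRON"
        elif s in _ADPS:
            pos[i] = "ADP"
        elif s in _CCONJS:
            pos[i] = "CCONJ"
        elif s in _ADJS:
            pos[i] = "ADJ"
        elif s.endswith("ly") and len(s) > 3:
            pos[i] = "ADV"

    def _next_open(i: int) -> int:
        j = i + 1
        while j < n and pos[j] in {"ADV", "ADJ", "DET", "NUM"}:
            j += 1
        return j

    # pass 2: open-class words with left/right context
    for i, s in enumerate(surfs):
        if pos[i] != "X":
            continue
        prev = pos[i - 1] if i > 0 else None
        prev_s = surfs[i - 1] if i > 0 else ""
        lem = _lemma(s, "VERB")
        nxt = _next_open(i)
        next_is_nounish = nxt < n and pos[nxt] == "X"
        if s.endswith("ing"):
            pos[i] = "ADJ" if next_is_nounish else "VERB"
        elif prev == "AUX" or (prev == "ADV" and i > 1 and pos[i - 2] == "AUX"):
            pos[i] = "VERB"
        elif prev == "PRON" and prev_s in _SUBJ_PRONS:
            pos[i] = "VERB" if lem in _VERBSET else "NOUN"
        elif prev_s == "to" and lem in _VERBSET and i >= 2 \
                and pos[i - 2] in {"VERB", "AUX", "ADV"}:
            pos[i] = "VERB"
        elif prev in {"DET", "ADJ", "NUM", "ADP"}:
            pos[i] = "NOUN"
        elif s == "to":
            pos[i] = "ADP"
        elif lem in _VERBSET and (s.endswith("ed") or s in _VERBSET
                                  or s in _IRREGULAR_LEMMA
                                  or (s.endswith("s") and lem in _VERBSET and prev != "VERB")):
            # verb-form shape; sentence-initial bare forms stay nominal
            pos[i] = "VERB" if prev is not None or s.endswith(("ed", "s")) else "NOUN"
        else:
            pos[i] = "NOUN"

    # "her": determiner when it introduces a noun phrase, pronoun otherwise
    for i, s in enumerate(surfs):
        if s == "her":
            nxt = i + 1
            if nxt < n and pos[nxt] in {"NOUN", "ADJ", "NUM"}:
                pos[i] = "DET"
            else:
                pos[i] = "PRON"
        elif s == "to" and i + 1 < n and pos[i + 1] == "VERB":
            pos[i] = "PART"
    return pos


# ---------------------------------------------------------------------------
# shallow dependency annotation
# ---------------------------------------------------------------------------


def _assign_deps(tokens: list[Token]) -> None:
    """Heuristic head/label assignment, one sentence at a time, in place."""
    by_sent: dict[int, list[Token]] = {}
    for t in tokens:
        by_sent.setdefault(t.sentence_id, []).append(t)
    for sent in by_sent.values():
        _deps_for_sentence(sent)
    _break_cycles(tokens)


def _deps_for_sentence(sent: list[Token]) -> None:
    idx = {t.index: k for k, t in enumerate(sent)}
    verbs = [t.index for t in sent if t.pos == "VERB"]
    root = verbs[0] if verbs else (
        next((t.index for t in sent if t.pos == "NOUN"), sent[0].index))

    def next_of(i: int, poses: set[str], limit: int | None = None) -> int | None:
        for t in sent[idx[i] + 1 :]:
            if limit is not None and t.index - i > limit:
                return None
            if t.pos in poses:
                return t.index
        return None

    def prev_of(i: int, poses: set[str]) -> int | None:
        for t in reversed(sent[: idx[i]]):
            if t.pos in poses:
                return t.index
        return None

    root_tok = sent[idx[root]]
    root_tok.head_index = root
    root_tok.dep_label = "ROOT"

    for t in sent:
        if t.index == root:
            continue
        s = t.lower
        if t.pos == "PUNCT" or t.pos == "SYM":
            t.head_index, t.dep_label = root, "punct"
        elif t.pos == "ADV" and s in _NEG_ADVS:
            h = next_of(t.index, {"VERB"}) or prev_of(t.index, {"VERB", "AUX"}) \
                or next_of(t.index, {"NOUN"}) or root
            t.head_index, t.dep_label = h, "neg"
        elif t.pos == "AUX":
            h = next_of(t.index, {"VERB"}) or root
            t.head_index, t.dep_label = h, "aux"
        elif t.pos == "PART":
            h = next_of(t.index, {"VERB"}) or root
            t.head_index, t.dep_label = h, "aux"
        elif t.pos == "DET":
            h = next_of(t.index, {"NOUN", "PRON"}) or root
            t.head_index, t.dep_label = h, "det"
        elif t.pos == "ADJ":
            h = next_of(t.index, {"NOUN"}, limit=3)
            if h is not None:
                t.head_index, t.dep_label = h, "amod"
            else:
                t.head_index, t.dep_label = prev_of(t.index, {"VERB"}) or root, "acomp"
        elif t.pos == "NUM":
            h = next_of(t.index, {"NOUN"}, limit=3) or prev_of(t.index, {"NOUN", "VERB"}) or root
            t.head_index, t.dep_label = h, "nummod"
        elif t.pos == "ADV":
            h = prev_of(t.index, {"VERB"}) or next_of(t.index, {"VERB"}) or root
            t.head_index, t.dep_label = h, "advmod"
        elif t.pos == "ADP":
            pv, pn = prev_of(t.index, {"VERB"}), prev_of(t.index, {"NOUN", "PRON"})
            if pv is None and pn is None:
                t.head_index, t.dep_label = root, "prep"
            elif pn is None or (pv is not None and pv > pn):
                t.head_index, t.dep_label = pv, "prep"
            else:
                t.head_index, t.dep_label = pn, "prep"
        elif t.pos == "CCONJ":
            t.head_index, t.dep_label = root, "cc"
        elif t.pos == "VERB":
            # verb chains: "report harming", "threatened to jump" -> xcomp
            k = idx[t.index]
            j = k - 1
            while j >= 0 and sent[j].pos in {"PART", "ADV", "AUX"}:
                j -= 1
            if j >= 0 and sent[j].pos == "VERB":
                t.head_index, t.dep_label = sent[j].index, "xcomp"
            elif j >= 0 and sent[j].pos == "CCONJ":
                pv = prev_of(t.index, {"VERB"})
                t.head_index, t.dep_label = (pv, "conj") if pv is not None else (root, "parataxis")
            else:
                pv = prev_of(t.index, {"VERB"})
                t.head_index, t.dep_label = (pv, "xcomp") if pv is not None else (root, "parataxis")
        elif t.pos in {"NOUN", "PRON"}:
            k = idx[t.index]
            nxt = sent[k + 1] if k + 1 < len(sent) else None
            if t.pos == "NOUN" and nxt is not None and nxt.pos == "NOUN":
                t.head_index, t.dep_label = nxt.index, "compound"
                continue
            pa = prev_of(t.index, {"ADP"})
            pv = prev_of(t.index, {"VERB"})
            if pa is not None and (pv is None or pa > pv):
                t.head_index, t.dep_label = pa, "pobj"
            elif pv is not None:
                t.head_index, t.dep_label = pv, "dobj"
            else:
                nv = next_of(t.index, {"VERB"})
                if nv is not None:
                    t.head_index, t.dep_label = nv, "nsubj"
                else:
                    t.head_index, t.dep_label = root, "dep"
        else:
            t.head_index, t.dep_label = root, "dep"


def _break_cycles(tokens: list[Token]) -> None:
    for t in tokens:
        seen = {t.index}
        cur = t
        for _ in range(len(tokens) + 1):
            if cur.head_index == cur.index:
                break
            nxt = tokens[cur.head_index]
            if nxt.index in seen:
                t.head_index, t.dep_label = t.index, "ROOT"
                break
            seen.add(nxt.index)
            cur = nxt


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def preprocess(
    text: str,
    user_id: str = "",
    doc_id: str = "",
    exceptions: Sequence[str] | None = None,
) -> AnnotatedDocument:
    """Run the full linguistic preprocessing layer over a note.

    Empty text yields a document with zero tokens and zero sentences.
    """
    if exceptions is None:
        exceptions = load_token_exceptions()
    raw = _raw_tokenise(text, exceptions)
    sids = _sentence_ids(raw, text)
    poses = _coarse_pos(raw)
    tokens = [
        Token(
            index=i,
            surface=surf,
            lemma=_lemma(surf, poses[i]),
            pos=poses[i],
            head_index=i,
            dep_label="dep",
            sentence_id=sids[i],
            char_start=start,
            char_end=end,
        )
        for i, (surf, start, end) in enumerate(raw)
    ]
    _assign_deps(tokens)
    return AnnotatedDocument(doc_id=doc_id, user_id=user_id, text=text, tokens=tokens)


def token_window(
    doc: AnnotatedDocument,
    span: tuple[int, int],
    width: int,
    sentence_bounded: bool = False,
) -> list[Token]:
    """Up to ``width`` tokens on each side of a token span (span excluded).

    The window is truncated at document boundaries and, when
    ``sentence_bounded``, additionally at the span's sentence boundaries.
    """
    start, end = span
    if not (0 <= start < end <= len(doc.tokens)):
        raise IndexError(f"span {span} out of bounds for {len(doc.tokens)} tokens")
    if width < 0:
        raise ValueError("width must be non-negative")
    lo = max(0, start - width)
    hi = min(len(doc.tokens), end + width)
    if sentence_bounded:
        s_lo, _ = doc.sentence_bounds(doc.tokens[start].sentence_id)
        _, s_hi = doc.sentence_bounds(doc.tokens[end - 1].sentence_id)
        lo, hi = max(lo, s_lo), min(hi, s_hi)
    return doc.tokens[lo:start] + doc.tokens[end:hi]


def governor(doc: AnnotatedDocument, token: Token) -> Token | None:
    """The syntactic head of ``token``, or None for a root."""
    if token.head_index == token.index:
        return None
    return doc.tokens[token.head_index]


def dependents(doc: AnnotatedDocument, index: int) -> list[Token]:
    """Tokens whose head is the token at ``index``."""
    return [t for t in doc.tokens if t.head_index == index and t.index != index]
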