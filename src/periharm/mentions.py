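"""Layer 3: create mention spans from grammar rules, apply exclusions, and
mark history sections.

Mention candidates come from every ``mention`` rule match; overlaps are
resolved longest-span first, then highest priority, then leftmost, yielding a
set of non-overlapping mentions.  ``exclude`` rules then cancel any mention
that overlaps their match and was created by a lower-priority rule — this is
how the ambiguous shorthand "OD" is dropped in dosage contexts ("Sertraline
50mg OD AM") while "2 x OD" survives, and how idiomatic "jump to conclusions"
is dropped while "jump through a window" survives.
"""

from __future__ import annotations

import re
from pathlib import Path

from .grammar import RulePattern, find_matches, load_rules
from .textmodel import AnnotatedDocument, Mention, _data_path

__all__ = [
    "detect_mentions",
    "apply_exclusions",
    "detect_history_sections",
    "load_history_headers",
]


def detect_mentions(
    doc: AnnotatedDocument, rules: list[RulePattern] | None = None
) -> AnnotatedDocument:
    """Populate ``doc.mentions`` from the ``mention`` rules (in place)."""
    if rules is None:
        rules = load_rules()
    candidates: list[tuple[int, int, RulePattern]] = []
    for rule in rules:
        if rule.action != "mention":
            continue
        for start, end in find_matches(doc, rule):
            candidates.append((start, end, rule))
    # longest span, then highest priority, then leftmost
    candidates.sort(key=lambda c: (-(c[1] - c[0]), -c[2].priority, c[0]))
    chosen: list[tuple[int, int, RulePattern]] = []
    for start, end, rule in candidates:
        if any(s < end and start < e for s, e, _ in chosen):
            continue
        chosen.append((start, end, rule))
    chosen.sort(key=lambda c: c[0])
    doc.mentions = [
        Mention(
            start=s,
            end=e,
            char_start=doc.tokens[s].char_start,
            char_end=doc.tokens[e - 1].char_end,
            rule_provenance=[rule.name],
        )
        for s, e, rule in chosen
    ]
    doc._mention_priorities = {(s, e): r.priority for s, e, r in chosen}  # type: ignore[attr-defined]
    return doc


def apply_exclusions(
    doc: AnnotatedDocument, rules: list[RulePattern] | None = None
) -> AnnotatedDocument:
    """Remove mentions cancelled by ``exclude`` rules (in place)."""
    if rules is None:
        rules = load_rules()
    priorities = getattr(doc, "_mention_priorities", {})
    for rule in rules:
        if rule.action != "exclude":
            continue
        for start, end in find_matches(doc, rule):
            kept = []
            for m in doc.mentions:
                overlaps = m.start < end and start < m.end
                creator_priority = priorities.get((m.start, m.end), 0)
                if overlaps and creator_priority < rule.priority:
                    continue
                kept.append(m)
            doc.mentions = kept
    return doc


# ---------------------------------------------------------------------------
# history sections
# ---------------------------------------------------------------------------


def load_history_headers(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Header list: (kind, text) with kind ``history`` or ``other``."""
    p = Path(path) if path is not None else _data_path("history_headers.txt")
    headers = []
    for line in p.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        kind, _, text = line.partition(":")
        kind, text = kind.strip().lower(), text.strip().lower()
        if kind not in {"history", "other"} or not text:
            raise ValueError(f"bad header line: {line!r}")
        headers.append((kind, text))
    # longer headers first so "past psychiatric history" beats "psychiatric history"
    headers.sort(key=lambda h: -len(h[1]))
    return headers


def _find_headers(doc: AnnotatedDocument, headers: list[tuple[str, str]]):
    """Yield (kind, token_start, token_end) for recognised ``Header:`` spans."""
    text_l = doc.text.lower()
    hits = []
    taken: list[tuple[int, int]] = []
    for kind, head in headers:
        for m in re.finditer(re.escape(head) + r"\s*:", text_l):
            # only at line start (possibly after whitespace) or sentence start
            pre = doc.text[: m.start()]
            # headers begin a line or sentence; a preceding colon covers the
            # degenerate back-to-back header case ("History: Plan: ...")
            at_line_start = not pre.rstrip(" \t") or \
                pre.rstrip(" \t").endswith(("\n", ".", "!", "?", ":"))
            if not at_line_start:
                continue
            if any(s <= m.start() < e for s, e in taken):
                continue
            taken.append((m.start(), m.end()))
            toks = [t.index for t in doc.tokens
                    if t.char_start >= m.start() and t.char_end <= m.end()]
            if toks:
                hits.append((kind, toks[0], toks[-1] + 1, m.start()))
    hits.sort(key=lambda h: h[3])
    return [(k, s, e) for k, s, e, _ in hits]


def detect_history_sections(
    doc: AnnotatedDocument, headers: list[tuple[str, str]] | None = None
) -> list[tuple[int, int]]:
    """Token spans (half-open) covered by history sections.

    A section opens after a history-type header and closes at the next
    recognised header (of either kind) or at document end.  The result is
    also stored on ``doc.history_sections``.
    """
    if headers is None:
        headers = load_history_headers()
    marks = _find_headers(doc, headers)
    sections: list[tuple[int, int]] = []
    n = len(doc.tokens)
    for i, (kind, _h_start, h_end) in enumerate(marks):
        if kind != "history":
            continue
        close = marks[i + 1][1] if i + 1 < len(marks) else n
        sections.append((h_end, close))
    doc.history_sections = sections
    return sections
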