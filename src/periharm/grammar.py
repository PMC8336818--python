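"""Declarative token-sequence rule patterns and their matcher.

A rule is a ``name ;; priority ;; action ;; pattern`` record.  The pattern is
a sequence of token constraints, each written as ``[key=value|value,...]``
with an optional quantifier ``?`` ``*`` ``+`` (bounded repetition).  Constraint
keys test token surface, lemma, coarse POS, dependency label, or semantic
category; ``key!=...`` negates the test and ``re=`` matches a regex against
the surface.  Example::

    harm_verb_obj ;; 60 ;; mention ;; [cat=HARM_ACTION,pos=VERB] [pos=DET]? [pos=NOUN|PRON]

Actions understood by the pipeline are ``mention`` (annotate the matched span
as a self-harm mention) and ``exclude`` (cancel lower-priority mentions that
overlap the matched span).  The matcher is a small backtracking engine that
returns the longest match anchored at each start position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .textmodel import AnnotatedDocument, Token, _data_path

_MAX_REPEAT = 6


class RuleSyntaxError(ValueError):
    pass


@dataclass(frozen=True)
class Constraint:
    key: str        # surface | lemma | pos | dep | cat | re
    values: tuple[str, ...]
    negated: bool = False
    quantifier: str = "1"   # "1", "?", "*", "+"

    def test(self, tok: Token, categories: set[str]) -> bool:
        if self.key == "surface":
            hit = tok.lower in self.values
        elif self.key == "lemma":
            hit = tok.lemma in self.values
        elif self.key == "pos":
            hit = tok.pos in self.values
        elif self.key == "dep":
            hit = tok.dep_label in self.values
        elif self.key == "cat":
            hit = bool(categories & set(self.values))
        elif self.key == "re":
            hit = any(re.fullmatch(v, tok.surface, re.IGNORECASE) for v in self.values)
        else:  # pragma: no cover - guarded at parse time
            raise RuleSyntaxError(f"unknown constraint key {self.key}")
        return not hit if self.negated else hit


@dataclass(frozen=True)
class PatternItem:
    """All constraints for one token position (conjunction)."""

    constraints: tuple[Constraint, ...]
    quantifier: str = "1"

    def test(self, tok: Token, categories: set[str]) -> bool:
        return all(c.test(tok, categories) for c in self.constraints)


@dataclass(frozen=True)
class RulePattern:
    name: str
    priority: int
    action: str
    pattern: tuple[PatternItem, ...]


_ITEM_RX = re.compile(r"\[([^\]]*)\]([?*+]?)")
_VALID_KEYS = {"surface", "lemma", "pos", "dep", "cat", "re"}


def parse_pattern(expr: str) -> tuple[PatternItem, ...]:
    items: list[PatternItem] = []
    pos = 0
    expr = expr.strip()
    while pos < len(expr):
        m = _ITEM_RX.match(expr, pos)
        if not m:
            raise RuleSyntaxError(f"bad pattern at {expr[pos:]!r}")
        body, quant = m.group(1), m.group(2) or "1"
        constraints = []
        for clause in body.split(","):
            clause = clause.strip()
            if not clause:
                continue
            if "!=" in clause:
                key, vals = clause.split("!=", 1)
                neg = True
            elif "=" in clause:
                key, vals = clause.split("=", 1)
                neg = False
            else:
                raise RuleSyntaxError(f"bad constraint {clause!r}")
            key = key.strip()
            if key not in _VALID_KEYS:
                raise RuleSyntaxError(f"unknown constraint key {key!r}")
            values = tuple(v.strip() if key in {"pos", "cat"} else v.strip().lower()
                           for v in vals.split("|"))
            constraints.append(Constraint(key, values, neg))
        if not constraints:
            raise RuleSyntaxError("empty constraint group")
        items.append(PatternItem(tuple(constraints), quant))
        pos = m.end()
        while pos < len(expr) and expr[pos].isspace():
            pos += 1
    if not items:
        raise RuleSyntaxError("empty pattern")
    return tuple(items)


def parse_rules(text: str) -> list[RulePattern]:
    rules: list[RulePattern] = []
    names: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(";;")]
        if len(parts) != 4:
            raise RuleSyntaxError(f"line {lineno}: expected 4 ';;' fields, got {len(parts)}")
        name, prio, action, patt = parts
        if name in names:
            raise RuleSyntaxError(f"line {lineno}: duplicate rule name {name!r}")
        names.add(name)
        if action not in {"mention", "exclude"}:
            raise RuleSyntaxError(f"line {lineno}: unknown action {action!r}")
        rules.append(RulePattern(name, int(prio), action, parse_pattern(patt)))
    return rules


def load_rules(path: str | Path | None = None) -> list[RulePattern]:
    p = Path(path) if path is not None else _data_path("rules.txt")
    return parse_rules(p.read_text(encoding="utf-8"))


def _match_from(
    doc: AnnotatedDocument,
    items: tuple[PatternItem, ...],
    item_i: int,
    tok_i: int,
    cats: list[set[str]],
) -> int | None:
    """Longest end index (exclusive) matching items[item_i:] from tok_i, or None."""
    if item_i == len(items):
        return tok_i
    item = items[item_i]
    n = len(doc.tokens)
    ends: list[int] = []
    if item.quantifier in {"?", "*"}:
        skipped = _match_from(doc, items, item_i + 1, tok_i, cats)
        if skipped is not None:
            ends.append(skipped)
    max_rep = 1 if item.quantifier in {"1", "?"} else _MAX_REPEAT
    j = tok_i
    reps = 0
    while j < n and reps < max_rep and item.test(doc.tokens[j], cats[j]):
        j += 1
        reps += 1
        rest = _match_from(doc, items, item_i + 1, j, cats)
        if rest is not None:
            ends.append(rest)
        if item.quantifier in {"1", "?"}:
            break
    return max(ends) if ends else None


def find_matches(
    doc: AnnotatedDocument, rule: RulePattern
) -> list[tuple[int, int]]:
    """All (start, end) token spans where the rule pattern matches, longest per start."""
    cats = [doc.tags_at(i) for i in range(len(doc.tokens))]
    out = []
    for i in range(len(doc.tokens)):
        end = _match_from(doc, rule.pattern, 0, i, cats)
        if end is not None and end > i:
            out.append((i, end))
    return out
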