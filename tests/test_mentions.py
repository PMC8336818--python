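"""Mention-span construction, exclusions and history sections."""

import pytest

from periharm.grammar import RuleSyntaxError, parse_pattern, parse_rules
from periharm.mentions import detect_history_sections


def _spans(pipeline, text):
    doc = pipeline.annotate(text)
    return [doc.text[m.char_start : m.char_end] for m in doc.mentions]


class TestSpanConstruction:
    @pytest.mark.parametrize("text, spans", [
        # indicative noun only, not the sentence
        ("she had scratches on her arm", ["scratches"]),
        # adjective keyword + modified noun
        ("she had a self-harming impulse", ["self-harming impulse"]),
        # verb keyword + direct-object pronoun
        ("she cut herself", ["cut herself"]),
        # passive fall after an active climb
        ("she climbed out a window and fell off", ["fell off"]),
        # direct synonym noun
        ("She took an overdose", ["overdose"]),
        # verb + determined body part
        ("She had cut her left wrist", ["cut her left wrist"]),
    ])
    def test_coding_rule_spans(self, pipeline, text, spans):
        assert _spans(pipeline, text) == spans

    def test_no_duplicate_spans(self, pipeline):
        doc = pipeline.annotate("She took an overdose and another overdose.")
        keys = [m.span_key() for m in doc.mentions]
        assert len(keys) == len(set(keys)) == 2

    def test_deterministic_order_stable(self, pipeline):
        text = "She cut herself. Previous episodes of self-harm. 2 x OD."
        a = pipeline.annotate(text).mentions
        b = pipeline.annotate(text).mentions
        assert [(m.start, m.end, m.rule_provenance) for m in a] == \
               [(m.start, m.end, m.rule_provenance) for m in b]


class TestExclusions:
    @pytest.mark.parametrize("text", [
        "Sertraline 50mg OD AM",           # once daily in the morning
        "Paracetamol 500mg OD",
        "tends to jump to conclusions",
        "She jumped down the stairs",
    ])
    def test_dosage_and_idiom_traps_yield_no_mention(self, pipeline, text):
        assert _spans(pipeline, text) == []

    @pytest.mark.parametrize("text, expect", [
        ("threatened to jump through a window", "jump"),
        ("2 x OD", "OD"),
    ])
    def test_valid_contexts_retained(self, pipeline, text, expect):
        assert any(expect in s for s in _spans(pipeline, text))

    def test_exclusion_spares_higher_priority_rule(self, pipeline):
        from periharm.grammar import RulePattern, parse_pattern
        from periharm.mentions import apply_exclusions, detect_mentions
        from periharm.lexicons import tag_semantics
        from periharm.textmodel import preprocess
        rules = [
            RulePattern("keep", 95, "mention", parse_pattern("[cat=SH]")),
            RulePattern("drop", 90, "exclude", parse_pattern("[cat=SH]")),
        ]
        doc = preprocess("She took an overdose")
        tag_semantics(doc, pipeline.lexicons)
        detect_mentions(doc, rules)
        apply_exclusions(doc, rules)
        assert len(doc.mentions) == 1


class TestHistorySections:
    def test_section_spans_to_next_header(self, pipeline):
        text = "Past psychiatric history: two overdoses. Current presentation: settled."
        doc = pipeline.annotate(text)
        assert len(doc.history_sections) == 1
        s, e = doc.history_sections[0]
        assert doc.span_text(s, e).strip() == "two overdoses."

    def test_no_headers_no_sections(self, pipeline):
        assert pipeline.annotate("She was seen at home.").history_sections == []

    def test_consecutive_headers_degenerate_first_section(self, pipeline):
        text = "Past psychiatric history: Forensic history: shoplifting offence."
        doc = pipeline.annotate(text)
        assert len(doc.history_sections) == 2
        first, second = doc.history_sections
        assert first[0] == first[1]           # empty section
        assert second[1] == len(doc.tokens)   # runs to document end

    def test_mention_in_history_section_is_historical(self, pipeline):
        doc = pipeline.annotate("Forensic history: she took an overdose then.")
        assert doc.mentions[0].temporality == "historical"


class TestRuleGrammar:
    def test_parse_roundtrip_and_validation(self):
        rules = parse_rules("r1 ;; 10 ;; mention ;; [cat=SH] [pos=NOUN]?\n")
        assert rules[0].name == "r1" and rules[0].priority == 10

    @pytest.mark.parametrize("bad", [
        "r1 ;; 10 ;; mention",                          # missing field
        "r1 ;; 10 ;; frobnicate ;; [cat=SH]",           # unknown action
        "r1 ;; 10 ;; mention ;; [wibble=SH]",           # unknown key
        "r1 ;; 10 ;; mention ;; [cat=SH]\nr1 ;; 9 ;; mention ;; [cat=SH]",
    ])
    def test_malformed_rules_raise(self, bad):
        with pytest.raises((RuleSyntaxError, ValueError)):
            parse_rules(bad)

    def test_empty_pattern_rejected(self):
        with pytest.raises(RuleSyntaxError):
            parse_pattern("   ")
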