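"""Linguistic preprocessing: tokenisation, offsets, windows, dependencies."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periharm.textmodel import (load_token_exceptions, preprocess,
                                token_window)


class TestTokenisation:
    def test_empty_text(self):
        doc = preprocess("")
        assert doc.tokens == [] and doc.n_sentences == 0

    @pytest.mark.parametrize("term", ["self-harm", "self-injury",
                                      "self-harming", "fh/o", "d/s/h"])
    def test_exception_terms_stay_single_tokens(self, term):
        doc = preprocess(f"She mentioned {term} yesterday.")
        assert term in [t.surface for t in doc.tokens]

    def test_hyphenated_term_not_split(self):
        doc = preprocess("She has a history of self-harm.")
        surfaces = [t.surface for t in doc.tokens]
        assert "self-harm" in surfaces
        assert "harm" not in surfaces

    def test_exception_not_matched_inside_longer_word(self):
        # "self-harming" must win over its prefix "self-harm"
        doc = preprocess("self-harming behaviour")
        assert doc.tokens[0].surface == "self-harming"

    def test_clitic_negation_split(self):
        doc = preprocess("She didn't cut herself.")
        surfaces = [t.lower for t in doc.tokens]
        assert "did" in surfaces and "n't" in surfaces

    def test_offsets_reconstruct_surfaces(self):
        text = "Past psychiatric history: two overdoses.\nSettled today."
        doc = preprocess(text)
        for t in doc.tokens:
            assert text[t.char_start : t.char_end] == t.surface

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet=st.characters(codec="ascii",
                                          exclude_categories=("Cc",)),
                   max_size=120))
    def test_offset_roundtrip_property(self, text):
        doc = preprocess(text, exceptions=load_token_exceptions())
        prev_end = -1
        for t in doc.tokens:
            assert t.char_start < t.char_end
            assert t.char_start >= prev_end
            assert text[t.char_start : t.char_end] == t.surface
            prev_end = t.char_end
        # nothing but whitespace falls between tokens
        consumed = set()
        for t in doc.tokens:
            consumed.update(range(t.char_start, t.char_end))
        for i, ch in enumerate(text):
            if i not in consumed:
                assert ch.isspace()


class TestSentencesAndHeads:
    def test_sentence_count(self):
        doc = preprocess("She cut herself. She was seen today.")
        assert doc.n_sentences == 2

    def test_head_links_stay_in_sentence_and_terminate(self):
        doc = preprocess("She took an overdose. Her mother was informed today.")
        for t in doc.tokens:
            assert doc.tokens[t.head_index].sentence_id == t.sentence_id
            # walking up terminates at a root
            cur, steps = t, 0
            while cur.head_index != cur.index:
                cur = doc.tokens[cur.head_index]
                steps += 1
                assert steps <= len(doc.tokens)

    def test_negation_dependency_frozen_parse(self):
        # frozen regression: "neg" attaches to the negated verb
        doc = preprocess("She did not cut herself.")
        neg = [t for t in doc.tokens if t.dep_label == "neg"]
        assert len(neg) == 1
        assert doc.tokens[neg[0].head_index].surface == "cut"

    def test_object_attachment_frozen_parse(self):
        doc = preprocess("she denies any self-harm")
        sh = next(t for t in doc.tokens if t.surface == "self-harm")
        assert doc.tokens[sh.head_index].surface == "denies"


class TestTokenWindow:
    def test_truncation_at_document_edges(self):
        doc = preprocess("one two three four five")
        window = token_window(doc, (2, 3), 10)
        assert [t.index for t in window] == [0, 1, 3, 4]

    def test_interior_window_arithmetic(self):
        doc = preprocess(" ".join(f"w{i}" for i in range(30)))
        window = token_window(doc, (14, 16), 10)
        assert [t.index for t in window] == list(range(4, 14)) + list(range(16, 26))

    def test_zero_width(self):
        doc = preprocess("one two three")
        assert token_window(doc, (1, 2), 0) == []

    def test_out_of_bounds_raises(self):
        doc = preprocess("one two")
        with pytest.raises(IndexError):
            token_window(doc, (1, 5), 3)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(1, 40), st.integers(0, 12), st.data())
    def test_window_size_bound(self, n, width, data):
        doc = preprocess(" ".join(f"w{i}" for i in range(n)))
        start = data.draw(st.integers(0, n - 1))
        end = data.draw(st.integers(start + 1, n))
        window = token_window(doc, (start, end), width)
        assert len(window) <= 2 * width
        if start >= width and n - end >= width:
            assert len(window) == 2 * width

    def test_sentence_bounded_variant(self):
        doc = preprocess("First sentence here. Target word now. Last sentence here.")
        target = next(t.index for t in doc.tokens if t.surface == "Target")
        bounded = token_window(doc, (target, target + 1), 10, sentence_bounded=True)
        assert all(t.sentence_id == 1 for t in bounded)
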