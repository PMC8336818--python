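"""XML annotation output and standoff import.

The tool's native output wraps each detected mention in an inline
``<mention>`` element carrying status/temporality/polarity and character
offsets; stripping the tags reproduces the note text exactly.  The schema
(periharm-1) is original to this package and versioned in the root element.

An importer for eHOST/Knowtator-style standoff XML is provided so manually
annotated reference standards can be scored: it reads ``annotation`` spans
and, when present, string slot values for the three attributes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from lxml import etree

from .evaluation import STANDOFF_COLUMNS
from .textmodel import AnnotatedDocument, Mention

SCHEMA_VERSION = "periharm-1"

__all__ = ["write_annotated_xml", "parse_annotated_xml", "read_ehost_xml",
           "SCHEMA_VERSION"]


def write_annotated_xml(doc: AnnotatedDocument) -> str:
    root = etree.Element("document", doc_id=doc.doc_id, user_id=doc.user_id,
                         schema=SCHEMA_VERSION)
    text_el = etree.SubElement(root, "text")
    mentions = sorted(doc.mentions, key=lambda m: m.char_start)
    pos = 0
    prev_el = None
    for m in mentions:
        chunk = doc.text[pos : m.char_start]
        if prev_el is None:
            text_el.text = (text_el.text or "") + chunk
        else:
            prev_el.tail = (prev_el.tail or "") + chunk
        m_el = etree.SubElement(
            text_el, "mention",
            status=m.status, temporality=m.temporality, polarity=m.polarity,
            char_start=str(m.char_start), char_end=str(m.char_end),
        )
        m_el.text = doc.text[m.char_start : m.char_end]
        prev_el = m_el
        pos = m.char_end
    tail = doc.text[pos:]
    if prev_el is None:
        text_el.text = (text_el.text or "") + tail
    else:
        prev_el.tail = (prev_el.tail or "") + tail
    return etree.tostring(root, encoding="unicode", pretty_print=False)


def parse_annotated_xml(xml_text: str) -> AnnotatedDocument:
    """Inverse of :func:`write_annotated_xml` (text, spans and attributes)."""
    root = etree.fromstring(xml_text.encode("utf-8"))
    if root.tag != "document":
        raise ValueError("not a periharm annotated document")
    text_el = root.find("text")
    text = "".join(text_el.itertext())
    doc = AnnotatedDocument(doc_id=root.get("doc_id", ""),
                            user_id=root.get("user_id", ""), text=text)
    for m_el in text_el.iter("mention"):
        doc.mentions.append(Mention(
            start=0, end=0,
            char_start=int(m_el.get("char_start")),
            char_end=int(m_el.get("char_end")),
            status=m_el.get("status"),
            temporality=m_el.get("temporality"),
            polarity=m_el.get("polarity"),
        ))
    return doc


_DEFAULT_ATTRS = {"status": "relevant", "temporality": "current",
                  "polarity": "positive"}


def read_ehost_xml(path: str | Path, doc_id: str | None = None) -> pd.DataFrame:
    """Standoff table from one eHOST/Knowtator annotations file.

    The document id defaults to the file's ``textSource`` minus its
    extension.  Attribute slots named status/temporality/polarity are read
    when present; anything missing falls back to the annotation defaults.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    if doc_id is None:
        src = root.get("textSource", Path(path).stem)
        doc_id = src.rsplit(".", 1)[0]
    slots: dict[str, tuple[str, str]] = {}
    for sm in root.iter("stringSlotMention"):
        slot = sm.find("mentionSlot")
        value = sm.find("stringSlotMentionValue")
        if slot is not None and value is not None:
            slots[sm.get("id")] = (slot.get("id", "").lower(), value.get("value", ""))
    class_slots: dict[str, dict[str, str]] = {}
    for cm in root.iter("classMention"):
        attrs = dict(_DEFAULT_ATTRS)
        for ref in cm.iter("hasSlotMention"):
            name, value = slots.get(ref.get("id"), ("", ""))
            if name in attrs and value:
                attrs[name] = value
        class_slots[cm.get("id")] = attrs
    rows = []
    for ann in root.iter("annotation"):
        span = ann.find("span")
        mention_ref = ann.find("mention")
        if span is None:
            continue
        attrs = class_slots.get(
            mention_ref.get("id") if mention_ref is not None else "",
            dict(_DEFAULT_ATTRS))
        rows.append({"doc_id": doc_id,
                     "char_start": int(span.get("start")),
                     "char_end": int(span.get("end")),
                     **attrs})
    return pd.DataFrame(rows, columns=STANDOFF_COLUMNS)
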