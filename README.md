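# periharm

Rule-based NLP detection of **perinatal self-harm** in free-text clinical
notes, for mental-health services research with electronic health records
(EHRs).

Structured EHR fields rarely capture acts of self-harm during pregnancy and
the postnatal year; the information sits in progress-note prose, where a
keyword search cannot tell "took an overdose last night" from "denies any
overdose", "thoughts of overdosing", "her mother took an overdose" or the
dosage shorthand "Sertraline 50mg OD AM". `periharm` finds self-harm
mentions and resolves three attributes per mention —

* **status**: `relevant` act vs `non-relevant` (ideation, risk language,
  third-party, conditional),
* **temporality**: `current` vs `historical`,
* **polarity**: `positive` vs `negative` (denied),

— via five sequential layers: linguistic preprocessing with clinical
tokenisation exceptions; semantic tagging against 13 curated lexicons;
a declarative token-sequence grammar for mention spans, exclusions and
history sections; dependency-based negation detection; and a ±10-token
contextual search for status/temporality cues.

A *true* mention is `(relevant, current, positive)`. At the service-user
level a user is flagged when ≥ k true mentions occur across all their notes
(k = 2 by default): real events are documented repeatedly at follow-up, so
the heuristic buys precision without deduplication. The evaluation module
provides the full battery used to validate such a tool: span and attribute
precision/recall/F (micro and macro), Cohen's κ, 2×2 confusion matrices,
positive/negative likelihood ratios with log-method 95% CIs, post-test
probabilities, and reconstruction of a confusion matrix from published
per-class summary statistics.

## Worked example

```python
from periharm import Pipeline, aggregate_users, mention_table

pipe = Pipeline()
notes = [
    ("n1", "u1", "She took an overdose last night."),
    ("n2", "u1", "Seen today. She cut herself deliberately."),
    ("n3", "u2", "Denies any self-harm. Possibility of self-harm discussed."),
]
docs = [pipe.annotate(text, user_id=u, doc_id=d) for d, u, text in notes]
print(mention_table(docs)[["doc_id", "text", "status", "temporality", "polarity"]])
for s in aggregate_users(docs, k=2):
    print(s.user_id, s.n_true_mentions, s.flagged_heuristic)
```

prints

```
  doc_id         text        status temporality  polarity
0     n1     overdose      relevant     current  positive
1     n2  cut herself      relevant     current  positive
2     n3    self-harm      relevant     current  negative
3     n3    self-harm  non-relevant     current  positive
u1 2 True
u2 0 False
```

User `u1` has two true mentions (an asserted current overdose and a current
deliberate act) and is flagged by the k = 2 heuristic; `u2`'s mentions are a
denial (negative polarity) and a hedged possibility (non-relevant status),
so `u2` is not flagged.

The same pipeline is available from the shell:

```bash
periharm annotate --corpus corpus.csv --mentions-out mentions.csv --xml-dir xml/
periharm aggregate --mentions mentions.csv --out users.csv -k 2
periharm evaluate --gold gold.csv --pred pred.csv --out report.json
periharm simulate --seed 7 --out-dir sim/
periharm run-all --seed 7 --out-dir run/
```

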