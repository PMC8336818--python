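# Methods

## The task

Acts of self-harm during pregnancy and the first postnatal year are
clinically important but poorly captured by structured fields in electronic
health records (EHRs); the evidence lives in free-text progress notes. A
keyword search over such notes cannot distinguish "took an overdose last
night" from "denies any overdose", "thoughts of overdosing", "her mother
took an overdose" or "Sertraline 50mg OD AM". `periharm` implements a
rule-based pipeline that finds self-harm *mentions* in note text and
resolves, for each mention, three attributes:

* **status** — `relevant` (an act by the patient) vs `non-relevant`
  (thoughts, risk language, conditional or third-party acts); `uncertain`
  exists in the data model for annotation tooling but the shipped rules
  never emit it,
* **temporality** — `current` (within roughly a month of the note) vs
  `historical`,
* **polarity** — `positive` (asserted) vs `negative` (denied/negated).

A *true* mention is `(relevant, current, positive)`. At the service-user
level, a user is flagged when they have at least k true mentions pooled over
all their notes, with k = 2 by default: a genuine self-harm event is a
significant clinical event and tends to be documented repeatedly at
follow-up, so requiring two mentions trades recall for precision without
deduplicating repeat documentation (which is deliberately kept — it is the
signal the heuristic exploits).

## Pipeline

Five layers run in order; each layer only consumes annotations added by
earlier layers.

1. **Linguistic preprocessing** (`textmodel`). Sentence detection,
   tokenisation, coarse POS tagging, lemmatisation, and shallow dependency
   annotation. The tokeniser applies a configurable exception list so
   clinical terms like `self-harm`, `self-injury`, `fh/o`, `d/s/h` survive
   as single tokens, keeps dose strings (`50mg`) whole, and splits `n't`
   clitics. The dependency layer is a deterministic rule-based annotator
   (closed-class word lists, suffix morphology, nearest-head attachment
   heuristics), not a trained parser. It produces exactly the relations the
   later layers need — `neg`, `nsubj`, `dobj`, `pobj`, `det`, `amod`,
   `aux`, `xcomp` — and is reliable on the short declarative sentences
   typical of psychiatric notes; it will mis-attach in long coordinated
   clauses, which is a known limitation.
2. **Lexical tagging** (`lexicons`). Thirteen curated lexicons (SH,
   BODY_PART, HARM_ACTION, FAMILY, HEDGING, INTENT, MED, MODALITY,
   NEGATION, R_SPEECH, LIFE_STAGE, PAST, PRESENT) tag tokens by lemma first
   and surface second, case-insensitively, so `deny` tags "Denies" and
   `suicide attempt` tags "suicide attempts". Multi-word terms match token
   sequences; the longest match wins; ties across categories stack. The
   shipped term lists are a seed reconstruction and are meant to be
   extended per deployment (`load_lexicons` takes any directory).
3. **Token-sequence grammar** (`grammar`, `mentions`). Declarative rules
   (`name ;; priority ;; action ;; pattern`) build mention spans following
   the span coding conventions: the indicative noun alone ("scratches"), an
   adjectival keyword plus its noun ("self-harming impulse"), a harm verb
   plus its reflexive object or determined body part ("cut herself", "cut
   her left wrist"), counted medication ingestion ("took 12 paracetamol
   tablets"). Overlapping candidates resolve longest-span, then
   highest-priority, then leftmost. `exclude` rules cancel lower-priority
   mentions they overlap: "OD" in dosage context (after a drug or dose, or
   before AM/PM/BD/TDS/nocte) and idiomatic "jump" ("to conclusions",
   "down the stairs") — while "2 x OD" and "jump through a window" survive.
   A separate header grammar marks history sections ("Past psychiatric
   history:" … up to the next recognised header).
4. **Negation detection** (`attributes.resolve_polarity`). A mention is
   negative when (a) one of its tokens heads a `neg` dependency, (b) its
   governor is a reported-speech verb that itself heads a `neg` dependency,
   (c) it is governed by a NEGATION-tagged word, including a negative
   determiner on its noun-phrase chain ("no history of suicide"), or
   (d) a negation symbol follows a colon after the mention
   ("Suicide attempts: X").
5. **Contextual search** (`attributes`). A window of `window_width` tokens
   (default 10) each side of the mention is scanned. HEDGING or MODALITY
   tags demote status to non-relevant; FAMILY linkage (kin token as clause
   subject or within three tokens to the left) marks third-party acts.
   PAST or LIFE_STAGE tags make temporality historical, as does an
   enclosing history section; "chronic" references stay current; when both
   PAST and PRESENT cues appear the nearest one wins with ties going to
   current (the global default is current); coordinated temporal modifiers
   with a PAST conjunct ("no current or past suicide attempts") are
   historical.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `window_width` | 10 tokens | contextual-search radius for status/temporality cues |
| `sentence_bounded_window` | off | truncate the window at sentence boundaries (ablation variant; the default is a pure token window) |
| `heuristic_k` | 2 | true mentions needed to flag a service user |
| `distinct_documents` | off | count at most one true mention per note towards k |
| `paper_faithful_mode` | off | see below |
| `span_match_mode` | exact | evaluation span-matching criterion (`overlap` available) |

`paper_faithful_mode` controls one deliberate behavioural choice: a
documented failure mode of windowed modality search is that a modal *after*
the mention ("she thought the self-harm would kill her") demotes a mention
it does not actually scope over. By default the pipeline only lets a
trailing modal demote when its verb takes the mention as a complement; the
flag restores the cruder any-modal-in-window behaviour for comparison.

## Evaluation machinery

Mention-level scoring pairs gold and predicted spans per document (`exact`
character equality, or `overlap` with greedy longest-overlap matching);
unmatched gold spans are FN, unmatched predictions FP. Attribute metrics
are computed over matched pairs only, so for a single-label attribute micro
precision = recall = F (= accuracy); macro averages are unweighted means
over classes present in the gold, skipping classes whose value is undefined.
Per-class precision/recall/F and Cohen's kappa are delegated to
scikit-learn; the test suite re-derives both with brute-force counting as an
independent oracle. Conventions: empty gold vs empty prediction scores 1.0;
undefined precision (no predicted positives) is reported as NaN with a flag.

User-level scoring reduces to a 2×2 confusion matrix, from which the
package computes per-class P/R/F, macro-F, kappa, positive and negative
likelihood ratios LR+ = sens/(1−spec) and LR− = (1−sens)/spec, their 95%
confidence intervals by the standard log-transform normal approximation
(exp(ln LR ± z·SE) with SE(ln LR+) = √(1/TP − 1/(TP+FN) + 1/FP −
1/(FP+TN)), symmetrically for LR−), and post-test probabilities by
converting pre-test odds through the LR. A specificity of exactly 1 yields
an infinite LR+ and is flagged rather than silently propagated — on a small
sample that is perfect-prediction pathology, not evidence.

`reconstruct_confusion` rebuilds TP/FP/FN/TN from published per-class
summary statistics (cohort size, gold positives, flagged count,
minority-class precision and recall). TP is implied twice — by
precision × flagged and by recall × gold-positives — and the two must agree
after rounding, otherwise the inputs are rejected with both candidates
reported. This is what lets the service-user statistics of a 152-user
development sample (29 gold-positive; with the k=2 heuristic 29 flagged at
minority precision/recall 0.69) be reproduced exactly: TP=20, FP=9, FN=9,
TN=114, hence LR+ 9.4, LR− 0.3, post-test probabilities 69.0% and 7.3%,
macro-F 0.81, kappa 0.62; without the heuristic (46 flagged, precision
0.57, recall 0.90) TP=26, FP=20, FN=3, TN=103 and LR+ 5.5.

## Synthetic data

Real psychiatric EHRs cannot ship with the package, so `fixtures` provides
two surfaces:

* `worked_example_bank()` — a frozen list of 31 short carrier sentences,
  one per linguistic phenomenon the rules implement (span constructions,
  each negation route, temporality cues, dosage/idiom traps), with the
  expected span and attributes. This is the primary regression surface and
  the pipeline is required to score 100% on it.
* `generate_corpus(FixtureSpec)` — a seeded generator assembling
  pseudo-notes from neutral filler sentences plus phenomenon templates,
  emitting gold standoff annotations by construction. Defaults mimic the
  reference cohort's shape: 50 users, 1–6 notes each, a user-level case
  probability of 0.19 (the reference prevalence of users with a true
  mention), and a per-note true-mention probability of 0.7 for cases so
  that most cases accrue more than one mention — the property that
  motivates the k=2 heuristic. A `class_mix` controls the proportions of
  plain-act, negated, hedged, historical, third-party, shorthand and
  exclusion-trap phenomena; degenerate mixes (e.g. 100% negated) simply
  generate nothing in the empty groups.

What passing on synthetic data shows — and what it does not: templates are
drawn from the same constructions the rules implement, so near-perfect
recovery demonstrates internal consistency of the five layers, aggregation
and scoring, not performance on real clinical language, whose spelling
variation, telegraphic shorthand and long coordinated sentences the
generator intentionally does not model. Performance claims on real notes
rest on the published development/test-set statistics, not on the
synthetic corpus.

## Numerical and design choices

* Character offsets are 0-based half-open everywhere, including standoff
  and XML I/O.
* Mention overlap resolution (longest span → priority → leftmost) and the
  rule that exclusions never cancel a higher-priority inclusion are fixed
  tie-breaks, tested as invariants.
* The k mentions for the heuristic are counted regardless of document by
  default (`distinct_documents` gives the stricter variant), since repeat
  documentation of one event is deliberately counted.
* Temporality uses cue words only; no date arithmetic is attempted against
  a delivery date or note timestamp. The one-month definition of "current"
  is therefore approximated by PRESENT-lexicon cues; this is a documented
  limitation.
* "risk to self" headers behave as risk-assessment context (the "risk"
  hedging cue demotes status); occasional use of that header for past
  events is a known error source.
* Kappa for a 2×2 machine-vs-gold comparison is computed from realised
  label vectors; when both raters agree perfectly on a single realised
  class it is defined as 1.0.
* Empty documents, documents with no mentions, and degenerate window
  widths (0) are all legal inputs and covered by tests.

## Known limitations

The dependency heuristics are shallow: clause-level scope (coordination,
relative clauses, reported speech chains) is approximated. Lexicons are
seed reconstructions, not exhaustive clinical vocabularies; recall on real
notes depends on extending them. Temporality remains the weakest attribute,
mirroring the low inter-annotator agreement that motivated marking events
current unless a clear historical marker is present.
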