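# Token-sequence grammar for self-harm mention detection.
# Format: name ;; priority ;; action ;; pattern
# See docs/methods.md for the pattern mini-grammar.  The rule inventory is a
# reconstruction built from the published span coding rules and error
# analysis; it is auditable and extendable.

# --- span construction -----------------------------------------------------
# adjective keyword + the noun it modifies ("self-harming impulse")
sh_adj_noun      ;; 60 ;; mention ;; [cat=SH,pos=ADJ] [pos=NOUN]
# multi-token SH term ("fell off", "suicide attempts")
sh_multi         ;; 58 ;; mention ;; [cat=SH] [cat=SH]+
# any token tagged SH: indicative nouns and direct synonyms
sh_tag           ;; 50 ;; mention ;; [cat=SH,pos!=VERB]
# verbal SH keyword standing alone ("she started self-harming")
sh_verb          ;; 45 ;; mention ;; [cat=SH,pos=VERB]
# harm verb + reflexive pronoun ("cut herself", "harming herself")
harm_verb_refl   ;; 60 ;; mention ;; [cat=HARM_ACTION,pos=VERB] [surface=herself|himself|themselves|myself|oneself]
# harm verb + determined body-part object ("cut her left wrist")
harm_verb_body   ;; 60 ;; mention ;; [cat=HARM_ACTION,pos=VERB] [pos=DET] [pos=ADJ|NUM]? [cat=BODY_PART]
# ingestion of a counted quantity of medication ("took 12 paracetamol tablets")
ingest_med       ;; 55 ;; mention ;; [lemma=take|swallow|ingest] [pos=NUM] [cat=MED] [lemma=tablet|pill|capsule]?
# "jump" + preposition + complement ("jump through a window")
jump_prep_obj    ;; 55 ;; mention ;; [lemma=jump] [pos=ADP] [pos=DET]? [pos=NOUN]
# bare "jump" as a harm verb ("threatened to jump to kill herself")
jump_bare        ;; 40 ;; mention ;; [lemma=jump,pos=VERB]

# --- false-positive exclusions --------------------------------------------
# "OD" as the dosage shorthand "once daily", not "overdose"
od_dose_after    ;; 90 ;; exclude ;; [cat=MED] [pos=NUM]? [surface=od]
od_dose_freq     ;; 90 ;; exclude ;; [surface=od] [surface=am|pm|bd|tds|qds|nocte|mane|prn]
od_dose_units    ;; 90 ;; exclude ;; [pos=NUM] [surface=od]
# idiomatic / non-harm uses of "jump"
jump_excl_idiom  ;; 90 ;; exclude ;; [lemma=jump] [surface=to] [surface=conclusion|conclusions]
jump_excl_stairs ;; 90 ;; exclude ;; [lemma=jump] [surface=down|up] [pos=DET]? [surface=stair|stairs|step|steps]
jump_excl_queue  ;; 90 ;; exclude ;; [lemma=jump] [pos=DET]? [surface=queue|gun|ship]
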