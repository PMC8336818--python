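# Section headers recognised in clinical notes.  Lines beginning "history:"
# open a history section; lines beginning "other:" close one.  Matching is
# case-insensitive at line starts, header text followed by a colon.
history: past psychiatric history
history: past medical history
history: previous psychiatric history
history: psychiatric history
history: forensic history
history: family history
history: personal history
history: medical history
history: background history
history: history of presenting complaint
history: previous episodes
other: current presentation
other: current episode
other: presenting complaint
other: mental state examination
other: mental state
other: risk assessment
other: current risk
other: impression
other: plan
other: medication
other: current medication
other: diagnosis
other: social circumstances
other: progress
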