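olanzapine
paracetamol
aspirin
sertraline
fluoxetine
citalopram
diazepam
quetiapine
lithium
ibuprofen
risperidone
venlafaxine
mirtazapine
zopiclone
promethazine
lamotrigine
codeine
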