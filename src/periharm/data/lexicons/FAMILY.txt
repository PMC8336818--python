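mother
father
daughter
son
sister
brother
aunt
uncle
grandmother
grandfather
cousin
husband
wife
partner
boyfriend
girlfriend
mum
dad
fh/o
friend
flatmate
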