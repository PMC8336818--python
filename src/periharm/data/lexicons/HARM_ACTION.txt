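cut
burn
hit
lacerate
jump
slash
stab
strangle
harm
hang
poison
electrocute
mutilate
kill
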