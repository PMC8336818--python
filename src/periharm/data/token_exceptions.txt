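# Multi-part clinical terms kept as single tokens by the tokeniser.
# One term per line; matching is case-insensitive at word boundaries.
self-harm
self-harmed
self-harming
self-injury
self-injurious
self-poisoning
self-mutilation
self-cutting
fh/o
d/s/h
s/h
h/o
p/w
o/e
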