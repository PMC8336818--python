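# Self-harm synonyms and shorthand (reconstruction seeded from the published
# category examples; extend via configuration).  "OD" is ambiguous shorthand
# for "overdose" and is disambiguated against dosage contexts by the grammar
# layer.
DSH
overdose
OD
self-harm
self-injury
self-poisoning
self-mutilation
self-cutting
d/s/h
suicide
suicide attempt
attempted suicide
scratch
laceration
fall off
ligature
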