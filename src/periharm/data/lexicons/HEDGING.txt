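plan
prone
risk
thought
ideation
urge
contemplate
tempted
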