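adolescent
adolescence
teenager
young
kid
teens
teenage
childhood
child
youth
schoolgirl
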