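could
would
possible
possibility
may
might
potential
potentially
perhaps
conditional
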