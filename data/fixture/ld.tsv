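rsid_a	rsid_b	r2
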