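cf_hz,ei
300,0.90
550,0.85
650,0.95
700,0.95
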