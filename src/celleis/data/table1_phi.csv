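diameter_um,phi_percent
4,0.0207
4.5,0.0242
5,0.0283
5.5,0.0331
6,0.0388
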