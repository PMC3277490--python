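# Anilide: aromatic N-H amide
[c][NX3;H1]C(=O)[#6]
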