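# N-methyl aromatic amine
[c][NX3;H1][CH3]
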