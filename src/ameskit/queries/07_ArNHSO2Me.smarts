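# Aryl methanesulfonamide
[c][NX3;H1]S(=O)(=O)[CH3]
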