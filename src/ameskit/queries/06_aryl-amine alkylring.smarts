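# ArN(CH2C)2: aryl nitrogen in an aliphatic ring flanked by two ring methylenes
[c][NX3;R]([CH2;R])[CH2;R]
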