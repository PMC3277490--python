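# Nitroaromatic: aromatic carbon bearing a nitro group (charged or neutral form)
c[$([NX3+](=O)[O-]),$([NX3](=O)=O)]
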