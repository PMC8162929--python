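condition,n_markers,n_contractions
sham,28,0
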