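team,n_trials
USA,32
Germany,347
the Netherlands,0
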