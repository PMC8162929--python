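condition,n_trials,correct,incorrect,ambiguous,no_response
nonlucid_rem,379,1,1,11,366
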