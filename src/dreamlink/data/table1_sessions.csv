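team,n_participants,sessions_twc,sessions_rem,sessions_svld,trials_twc
USA,22,16,12,6,31
Germany,10,60,40,5,54
France,1,2,2,2,65
the Netherlands,3,4,3,2,8
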