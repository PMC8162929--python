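team,task,total_trials,correct,incorrect,ambiguous,no_response
USA,math problems,31,6,1,5,19
Germany,math problems in Morse code and Morse-code eye movements,4,0,0,0,4
Germany,math problems in Morse code and LR eye movements,50,1,2,2,45
France,counting (tactile),13,7,2,2,2
France,sound discrimination,4,0,0,2,2
France,light discrimination,4,0,0,0,4
France,semantic discrimination,39,12,0,14,13
France,yes/no questions,5,2,0,2,1
the Netherlands,math problems,8,1,0,1,6
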