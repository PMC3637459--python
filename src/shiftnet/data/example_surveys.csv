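shift_id,respondent,relation,target,frequency
W08-day,C,medication_advice,A,4
W08-day,C,medication_advice,B,2
W08-day,C,medication_advice,D,7
W08-day,D,medication_advice,A,1
W08-day,D,medication_advice,B,10+
W08-day,A,medication_advice,B,0
W08-day,B,medication_advice,A,0
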