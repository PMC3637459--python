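shift_id,date,shift,person_id,role
W08-day,2009-06-24,PM,A,SRN
W08-day,2009-06-24,PM,B,PCT
W08-day,2009-06-24,PM,C,CRN
W08-day,2009-06-24,PM,D,SRN
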