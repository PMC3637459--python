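shift_id,completed,refused,not_located
W01-night,10,1,3
W01-day,17,1,2
W02-night,8,1,0
W02-day,11,4,3
W03-night,11,2,0
W03-day,7,9,0
W04-night,13,0,0
W04-day,14,5,1
W05-night,10,1,0
W05-day,13,4,2
W06-night,14,1,0
W06-day,19,3,0
W07-night,14,0,0
W07-day,18,3,0
W08-night,14,1,0
W08-day,18,3,0
W09-night,14,1,0
W09-day,15,5,2
W10-night,14,1,0
W10-day,20,4,0
W11-night,15,2,0
W11-day,19,3,0
W12-night,14,0,0
W12-day,14,6,0
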