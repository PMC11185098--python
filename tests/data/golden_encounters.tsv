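person_id	item_id	y	rt_seconds	ac_count	tr_count	iv_count
p1	1	1	12.5	1	1	0
p1	2	0	8	0	0	1
p1	FILLER		1.5	0	0	0
p2	1	0	20	0	2	0
p2	2	1	6	2	0	0
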