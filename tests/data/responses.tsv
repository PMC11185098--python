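person_id	item_id	y
p1	1	1
p1	2	0
p2	1	0
p2	2	1
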