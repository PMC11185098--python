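person_id	seq	timestamp_ms	kind	page_id	page_kind	task_id	item_id	option_id
p1	1	0	navigate	T1.P000	text	T1		
p1	2	2000	navigate	T1.P010	item	T1	1	
p1	3	2300	navigate	T1.P020	item	T1	2	
p1	4	2400	select_option	T1.P020	item	T1	2	A
p1	5	6300	navigate	T1.P900	item	T1	FILLER	
p1	6	7800	navigate	T1.P020	item	T1	2	
p1	7	11800	navigate	T1.P010	item	T1	1	
p1	8	11900	select_option	T1.P010	item	T1	1	A
p1	9	12000	select_option	T1.P010	item	T1	1	B
p1	10	18050	navigate	T1.P000	text	T1		
p1	11	19550	navigate	T1.P010	item	T1	1	
p1	12	25800	navigate	T1.P990	other	T1		
p2	1	0	navigate	T1.P000	text	T1		
p2	2	2000	navigate	T1.P010	item	T1	1	
p2	3	2300	navigate	T1.P020	item	T1	2	
p2	4	2400	select_option	T1.P020	item	T1	2	A
p2	5	2500	select_option	T1.P020	item	T1	2	B
p2	6	2600	select_option	T1.P020	item	T1	2	A
p2	7	8300	navigate	T1.P010	item	T1	1	
p2	8	8400	select_option	T1.P010	item	T1	1	A
p2	9	14968	navigate	T1.P000	text	T1		
p2	10	16468	navigate	T1.P010	item	T1	1	
p2	11	23134	navigate	T1.P000	text	T1		
p2	12	24634	navigate	T1.P010	item	T1	1	
p2	13	31300	navigate	T1.P990	other	T1		
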