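gene	allele	rsid	chrom	pos	ref	alt	function	activity_value
CYP2D6	*1						normal	1
CYP2D6	*3	rs35742686	22	42524244	AG	A	none	0
CYP2D6	*4	rs1065852	22	42526694	G	A	none	0
CYP2D6	*4	rs3892097	22	42524947	C	T	none	0
CYP2D6	*6	rs5030655	22	42525085	TA	T	none	0
CYP2D6	*9	rs5030656	22	42524175	TCTT	T	decreased	0.5
CYP2D6	*10	rs1065852	22	42526694	G	A	decreased	0.5
CYP2D6	*17	rs28371706	22	42525772	G	A	decreased	0.5
CYP2D6	*41	rs28371725	22	42523805	C	T	decreased	0.5
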