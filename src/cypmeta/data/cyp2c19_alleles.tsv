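gene	allele	rsid	chrom	pos	ref	alt	function	activity_value
CYP2C19	*1						normal	
CYP2C19	*2	rs4244285	10	96541616	G	A	none	
CYP2C19	*3	rs4986893	10	96540410	G	A	none	
CYP2C19	*17	rs12248560	10	96521657	C	T	increased	
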