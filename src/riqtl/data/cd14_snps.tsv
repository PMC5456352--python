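snp_id	chromosome	position_Mb	alleles	gene	exon	function	b6_allele	d2_allele
wt37-18-36885521	18	36.885521	C/T	Cd14	2	Synonymous	C	T
rs8255713	18	36.885972	T/A	Cd14	2	Nonsynonymous	T	A
rs8255712	18	36.885973	C/G	Cd14	2	Nonsynonymous	C	G
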