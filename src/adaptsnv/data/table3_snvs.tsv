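position	gene_order	ref_base	alt_base	ref_codon	alt_codon	ref_aa	alt_aa	mutation_type	protein
340649	340	C	T	GAG	AAG	E	K	N	30S ribosomal protein S5
933317	NA	G	A	NA	NA	NA	NA	noncoding	NA
936527	909	A	G	GAT	GAC	D	D	S	Phosphohydrolase
948824	NA	A	G	NA	NA	NA	NA	noncoding	NA
1075051	1048	T	C	GAU	GAC	D	D	S	Sensor histidine kinase KdpD
1075054	1048	G	A	GAG	GAA	E	E	S	Sensor histidine kinase KdpD
2322761	NA	G	A	NA	NA	NA	NA	noncoding	NA
2322857	2245	C	A	GAG	GAU	E	D	N	Ferritin
2330661	2256	A	G	GGU	GGC	G	G	S	FprA family A-type flavoprotein
2330741	2256	G	T	CUC	AUC	L	I	N	FprA family A-type flavoprotein
2335191	2263	G	A	CAC	CAU	H	H	S	Nitroreductase family protein
2335334	2263	C	T	GCC	ACC	A	T	N	Nitroreductase family protein
2335385	2263	G	A	CGC	UGC	R	C	N	Nitroreductase family protein
2336242	2264	T	C	GCA	GCG	A	A	S	Ribonucleotide-diphosphate reductase subunitbeta
2360360	2288	T	C	AAC	AGC	N	S	N	Peptidase S24
2498766	2293	C	T	GCU	ACU	A	T	N	Type II toxin-antitoxin system PemK/MazF family toxin
2499857	NA	T	G	NA	NA	NA	NA	noncoding	NA
2359643	NA	A	C	NA	NA	NA	NA	noncoding	NA
2360322	2288	C	T	GAA	AAA	E	K	N	Peptidase S24
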