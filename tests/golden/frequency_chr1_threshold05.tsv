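chrom	pos	alt	count	n_samples	frequency	samples	survives
1	1000	G	3	3	1.0	S1,S2,S3	True
1	2000	T	2	3	0.6666666666666666	S1,S2	True
1	3000	A	1	3	0.3333333333333333	S1	False
1	4000	C	1	3	0.3333333333333333	S2	False
1	5000	C	1	3	0.3333333333333333	S3	False
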