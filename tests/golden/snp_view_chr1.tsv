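chrom	pos	alt	S1	S2	S3	samples
1	1000	G	1	1	1	S1,S2,S3
1	2000	T	1	1	0	S1,S2
1	3000	A	1	0	0	S1
1	4000	C	0	1	0	S2
1	5000	C	0	0	1	S3
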