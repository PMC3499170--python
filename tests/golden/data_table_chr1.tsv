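sample_id	chrom	pos	ref	alt	score	score_missing	reads_A	reads_C	reads_G	reads_T	mutant_fraction	mutant_pct	zygosity	extras
S1	1	1000	A	G	50.0	False	10	0	10	0	0.5	50.0	het	
S1	1	2000	C	T	60.0	False	0	12	0	8	0.4	40.0	het	
S1	1	3000	G	A	40.0	False	18	0	2	0	0.9	90.0	hom_alt	
S2	1	1000	A	G	55.0	False	0	0	20	0	1.0	100.0	hom_alt	
S2	1	2000	C	T	45.0	False	0	10	0	10	0.5	50.0	het	
S2	1	4000	T	C	35.0	False	0	22	0	0	1.0	100.0	hom_alt	
S3	1	1000	A	G	0.0	True	9	0	11	0	0.55	55.0	het	
S3	1	5000	A	C	65.0	False	5	15	0	0	0.75	75.0	het	
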