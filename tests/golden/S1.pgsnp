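track type=pgSnp visibility=3 name="S1" description="SNP calls"
chr1	999	1000	A/G	2	10,10	50,50
chr1	1999	2000	C/T	2	12,8	60,60
chr1	2999	3000	G/A	2	2,18	40,40
chr2	99	100	G	1	15	70
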