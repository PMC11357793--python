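scenario	n_per_group	effect_size	sim	celltype	stratum	metric	cutoff	value
n10_es0	10	0.0	0	0	all	power	q<0.05	
n10_es0	10	0.0	0	0	1	power	q<0.05	
n10_es0	10	0.0	0	0	2	power	q<0.05	
n10_es0	10	0.0	0	0	3	power	q<0.05	
n10_es0	10	0.0	0	0	4	power	q<0.05	
n10_es0	10	0.0	0	0	5	power	q<0.05	
n10_es0	10	0.0	0	0	6	power	q<0.05	
n10_es0	10	0.0	0	0	7	power	q<0.05	
n10_es0	10	0.0	0	0	8	power	q<0.05	
n10_es0	10	0.0	0	0	9	power	q<0.05	
n10_es0	10	0.0	0	1	all	power	q<0.05	
n10_es0	10	0.0	0	1	1	power	q<0.05	
n10_es0	10	0.0	0	1	2	power	q<0.05	
n10_es0	10	0.0	0	1	3	power	q<0.05	
n10_es0	10	0.0	0	1	4	power	q<0.05	
n10_es0	10	0.0	0	1	5	power	q<0.05	
n10_es0	10	0.0	0	1	6	power	q<0.05	
n10_es0	10	0.0	0	1	7	power	q<0.05	
n10_es0	10	0.0	0	1	8	power	q<0.05	
n10_es0	10	0.0	0	1	9	power	q<0.05	
n10_es0	10	0.0	0	2	all	power	q<0.05	
n10_es0	10	0.0	0	2	1	power	q<0.05	
n10_es0	10	0.0	0	2	2	power	q<0.05	
n10_es0	10	0.0	0	2	3	power	q<0.05	
n10_es0	10	0.0	0	2	4	power	q<0.05	
n10_es0	10	0.0	0	2	5	power	q<0.05	
n10_es0	10	0.0	0	2	6	power	q<0.05	
n10_es0	10	0.0	0	2	7	power	q<0.05	
n10_es0	10	0.0	0	2	8	power	q<0.05	
n10_es0	10	0.0	0	2	9	power	q<0.05	
n10_es0	10	0.0	0	0	all	fdr	q<0.05	
n10_es0	10	0.0	0	1	all	fdr	q<0.05	
n10_es0	10	0.0	0	2	all	fdr	q<0.05	
n10_es0	10	0.0	0	0	all	fdc	q<0.05	
n10_es0	10	0.0	0	1	all	fdc	q<0.05	
n10_es0	10	0.0	0	2	all	fdc	q<0.05	
n10_es0	10	0.0	0	0	all	tdr	top50	0.0
n10_es0	10	0.0	0	0	all	tdr	top100	0.0
n10_es0	10	0.0	0	1	all	tdr	top50	0.0
n10_es0	10	0.0	0	1	all	tdr	top100	0.0
n10_es0	10	0.0	0	2	all	tdr	top50	0.0
n10_es0	10	0.0	0	2	all	tdr	top100	0.0
n10_es0	10	0.0	0	0	all	fdc	top50	inf
n10_es0	10	0.0	0	0	all	fdc	top100	inf
n10_es0	10	0.0	0	1	all	fdc	top50	inf
n10_es0	10	0.0	0	1	all	fdc	top100	inf
n10_es0	10	0.0	0	2	all	fdc	top50	inf
n10_es0	10	0.0	0	2	all	fdc	top100	inf
n10_es0	10	0.0	1	0	all	power	q<0.05	
n10_es0	10	0.0	1	0	1	power	q<0.05	
n10_es0	10	0.0	1	0	2	power	q<0.05	
n10_es0	10	0.0	1	0	3	power	q<0.05	
n10_es0	10	0.0	1	0	4	power	q<0.05	
n10_es0	10	0.0	1	0	5	power	q<0.05	
n10_es0	10	0.0	1	0	6	power	q<0.05	
n10_es0	10	0.0	1	0	7	power	q<0.05	
n10_es0	10	0.0	1	0	8	power	q<0.05	
n10_es0	10	0.0	1	0	9	power	q<0.05	
n10_es0	10	0.0	1	1	all	power	q<0.05	
n10_es0	10	0.0	1	1	1	power	q<0.05	
n10_es0	10	0.0	1	1	2	power	q<0.05	
n10_es0	10	0.0	1	1	3	power	q<0.05	
n10_es0	10	0.0	1	1	4	power	q<0.05	
n10_es0	10	0.0	1	1	5	power	q<0.05	
n10_es0	10	0.0	1	1	6	power	q<0.05	
n10_es0	10	0.0	1	1	7	power	q<0.05	
n10_es0	10	0.0	1	1	8	power	q<0.05	
n10_es0	10	0.0	1	1	9	power	q<0.05	
n10_es0	10	0.0	1	2	all	power	q<0.05	
n10_es0	10	0.0	1	2	1	power	q<0.05	
n10_es0	10	0.0	1	2	2	power	q<0.05	
n10_es0	10	0.0	1	2	3	power	q<0.05	
n10_es0	10	0.0	1	2	4	power	q<0.05	
n10_es0	10	0.0	1	2	5	power	q<0.05	
n10_es0	10	0.0	1	2	6	power	q<0.05	
n10_es0	10	0.0	1	2	7	power	q<0.05	
n10_es0	10	0.0	1	2	8	power	q<0.05	
n10_es0	10	0.0	1	2	9	power	q<0.05	
n10_es0	10	0.0	1	0	all	fdr	q<0.05	
n10_es0	10	0.0	1	1	all	fdr	q<0.05	
n10_es0	10	0.0	1	2	all	fdr	q<0.05	
n10_es0	10	0.0	1	0	all	fdc	q<0.05	
n10_es0	10	0.0	1	1	all	fdc	q<0.05	
n10_es0	10	0.0	1	2	all	fdc	q<0.05	
n10_es0	10	0.0	1	0	all	tdr	top50	0.0
n10_es0	10	0.0	1	0	all	tdr	top100	0.0
n10_es0	10	0.0	1	1	all	tdr	top50	0.0
n10_es0	10	0.0	1	1	all	tdr	top100	0.0
n10_es0	10	0.0	1	2	all	tdr	top50	0.0
n10_es0	10	0.0	1	2	all	tdr	top100	0.0
n10_es0	10	0.0	1	0	all	fdc	top50	inf
n10_es0	10	0.0	1	0	all	fdc	top100	inf
n10_es0	10	0.0	1	1	all	fdc	top50	inf
n10_es0	10	0.0	1	1	all	fdc	top100	inf
n10_es0	10	0.0	1	2	all	fdc	top50	inf
n10_es0	10	0.0	1	2	all	fdc	top100	inf
n10_es0.5	10	0.5	0	0	all	power	q<0.05	0.0
n10_es0.5	10	0.5	0	0	1	power	q<0.05	0.0
n10_es0.5	10	0.5	0	0	2	power	q<0.05	
n10_es0.5	10	0.5	0	0	3	power	q<0.05	
n10_es0.5	10	0.5	0	0	4	power	q<0.05	
n10_es0.5	10	0.5	0	0	5	power	q<0.05	0.0
n10_es0.5	10	0.5	0	0	6	power	q<0.05	
n10_es0.5	10	0.5	0	0	7	power	q<0.05	
n10_es0.5	10	0.5	0	0	8	power	q<0.05	
n10_es0.5	10	0.5	0	0	9	power	q<0.05	0.0
n10_es0.5	10	0.5	0	1	all	power	q<0.05	0.0
n10_es0.5	10	0.5	0	1	1	power	q<0.05	0.0
n10_es0.5	10	0.5	0	1	2	power	q<0.05	0.0
n10_es0.5	10	0.5	0	1	3	power	q<0.05	
n10_es0.5	10	0.5	0	1	4	power	q<0.05	
n10_es0.5	10	0.5	0	1	5	power	q<0.05	0.0
n10_es0.5	10	0.5	0	1	6	power	q<0.05	0.0
n10_es0.5	10	0.5	0	1	7	power	q<0.05	0.0
n10_es0.5	10	0.5	0	1	8	power	q<0.05	
n10_es0.5	10	0.5	0	1	9	power	q<0.05	
n10_es0.5	10	0.5	0	2	all	power	q<0.05	0.0
n10_es0.5	10	0.5	0	2	1	power	q<0.05	0.0
n10_es0.5	10	0.5	0	2	2	power	q<0.05	
n10_es0.5	10	0.5	0	2	3	power	q<0.05	
n10_es0.5	10	0.5	0	2	4	power	q<0.05	
n10_es0.5	10	0.5	0	2	5	power	q<0.05	0.0
n10_es0.5	10	0.5	0	2	6	power	q<0.05	
n10_es0.5	10	0.5	0	2	7	power	q<0.05	
n10_es0.5	10	0.5	0	2	8	power	q<0.05	
n10_es0.5	10	0.5	0	2	9	power	q<0.05	
n10_es0.5	10	0.5	0	0	all	fdr	q<0.05	
n10_es0.5	10	0.5	0	1	all	fdr	q<0.05	
n10_es0.5	10	0.5	0	2	all	fdr	q<0.05	
n10_es0.5	10	0.5	0	0	all	fdc	q<0.05	
n10_es0.5	10	0.5	0	1	all	fdc	q<0.05	
n10_es0.5	10	0.5	0	2	all	fdc	q<0.05	
n10_es0.5	10	0.5	0	0	all	tdr	top50	0.0
n10_es0.5	10	0.5	0	0	all	tdr	top100	0.01
n10_es0.5	10	0.5	0	1	all	tdr	top50	0.04
n10_es0.5	10	0.5	0	1	all	tdr	top100	0.03
n10_es0.5	10	0.5	0	2	all	tdr	top50	0.02
n10_es0.5	10	0.5	0	2	all	tdr	top100	0.01
n10_es0.5	10	0.5	0	0	all	fdc	top50	inf
n10_es0.5	10	0.5	0	0	all	fdc	top100	99.0
n10_es0.5	10	0.5	0	1	all	fdc	top50	24.0
n10_es0.5	10	0.5	0	1	all	fdc	top100	32.333333333333336
n10_es0.5	10	0.5	0	2	all	fdc	top50	49.0
n10_es0.5	10	0.5	0	2	all	fdc	top100	99.0
n10_es0.5	10	0.5	1	0	all	power	q<0.05	0.0
n10_es0.5	10	0.5	1	0	1	power	q<0.05	
n10_es0.5	10	0.5	1	0	2	power	q<0.05	
n10_es0.5	10	0.5	1	0	3	power	q<0.05	
n10_es0.5	10	0.5	1	0	4	power	q<0.05	
n10_es0.5	10	0.5	1	0	5	power	q<0.05	
n10_es0.5	10	0.5	1	0	6	power	q<0.05	
n10_es0.5	10	0.5	1	0	7	power	q<0.05	
n10_es0.5	10	0.5	1	0	8	power	q<0.05	0.0
n10_es0.5	10	0.5	1	0	9	power	q<0.05	
n10_es0.5	10	0.5	1	1	all	power	q<0.05	0.0
n10_es0.5	10	0.5	1	1	1	power	q<0.05	0.0
n10_es0.5	10	0.5	1	1	2	power	q<0.05	
n10_es0.5	10	0.5	1	1	3	power	q<0.05	0.0
n10_es0.5	10	0.5	1	1	4	power	q<0.05	0.0
n10_es0.5	10	0.5	1	1	5	power	q<0.05	
n10_es0.5	10	0.5	1	1	6	power	q<0.05	0.0
n10_es0.5	10	0.5	1	1	7	power	q<0.05	
n10_es0.5	10	0.5	1	1	8	power	q<0.05	
n10_es0.5	10	0.5	1	1	9	power	q<0.05	
n10_es0.5	10	0.5	1	2	all	power	q<0.05	0.0
n10_es0.5	10	0.5	1	2	1	power	q<0.05	0.0
n10_es0.5	10	0.5	1	2	2	power	q<0.05	
n10_es0.5	10	0.5	1	2	3	power	q<0.05	0.0
n10_es0.5	10	0.5	1	2	4	power	q<0.05	0.0
n10_es0.5	10	0.5	1	2	5	power	q<0.05	0.0
n10_es0.5	10	0.5	1	2	6	power	q<0.05	0.0
n10_es0.5	10	0.5	1	2	7	power	q<0.05	0.0
n10_es0.5	10	0.5	1	2	8	power	q<0.05	0.0
n10_es0.5	10	0.5	1	2	9	power	q<0.05	
n10_es0.5	10	0.5	1	0	all	fdr	q<0.05	
n10_es0.5	10	0.5	1	1	all	fdr	q<0.05	
n10_es0.5	10	0.5	1	2	all	fdr	q<0.05	1.0
n10_es0.5	10	0.5	1	0	all	fdc	q<0.05	
n10_es0.5	10	0.5	1	1	all	fdc	q<0.05	
n10_es0.5	10	0.5	1	2	all	fdc	q<0.05	inf
n10_es0.5	10	0.5	1	0	all	tdr	top50	0.0
n10_es0.5	10	0.5	1	0	all	tdr	top100	0.0
n10_es0.5	10	0.5	1	1	all	tdr	top50	0.02
n10_es0.5	10	0.5	1	1	all	tdr	top100	0.01
n10_es0.5	10	0.5	1	2	all	tdr	top50	0.1
n10_es0.5	10	0.5	1	2	all	tdr	top100	0.08
n10_es0.5	10	0.5	1	0	all	fdc	top50	inf
n10_es0.5	10	0.5	1	0	all	fdc	top100	inf
n10_es0.5	10	0.5	1	1	all	fdc	top50	49.0
n10_es0.5	10	0.5	1	1	all	fdc	top100	99.0
n10_es0.5	10	0.5	1	2	all	fdc	top50	9.0
n10_es0.5	10	0.5	1	2	all	fdc	top100	11.5
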