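table	row	comp	raw	native	universal	region	wt	sub	species	location	site	figures	ref
4	1	1	I249/1k7A	249	1k7		I	A	Aedes aegypti	PyR2, PyR1	beyond	5d	B11
4	2	1	S420/1i29A	420	1i29		S	A	Aedes aegypti	PyR1	beyond	5e	B12
4	3	1	D823G/A/K	823			D	G/A/K	Blattella germanica	PyR1	beyond	5a	B82
4	4	1	L914/2k7F/I	914	2k7		L	F/I	Drosophila melanogaster	PyR1	beyond	6f	B68
4	5	1	N927/2o8I	927	2o8		N	I	Drosophila melanogaster	PyR1, PyR2	beyond	5f	B68
4	6	1	A1410/3k10V	1410	3k10		A	V	Blattella germanica	PyR1	beyond	6a	B85
4	7	1	A1494/3p47V	1494	3p47		A	V	Blattella germanica	PyR1	beyond	6b	B85
4	8	1	G1535/3i14A	1535	3i14		G	A	Blattella germanica	PyR1	beyond		B69
4	9	1	N1541/3i20A	1541	3i20		N	A	Blattella germanica	PyR1	beyond		B69
4	10	1	D1549/3i28V	1549	3i28		D	V	Blattella germanica		beyond	6e	B86
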