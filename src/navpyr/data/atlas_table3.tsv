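table	row	comp	raw	native	universal	region	wt	sub	species	location	site	figures	ref
3	1	1	D59G	59			D	G	Blattella germanica		linker/other		B43
3	2	1	A99S	99			A	S	Culex quinquefasciatus		linker/other		B75
3	3	1	I254/1k12N	254	1k12		I	N	Drosophila melanogaster		beyond		B76
3	4	1	E435/1i45K	435	1i45		E	K	Blattella germanica		beyond		B43
3	5	1	C785R	785			C	R	Blattella germanica		linker/other		B43
3	6	1	M827I	827		IIS1-S2	M	I	P. humanus capitis	PyR1	beyond	5a	B58
3	7	1	G943/2o24A	943	2o24		G	A	P. humanus capitis	PyR1, PyR2	beyond	5b	B77
3	8	1	Q945/2o26R	945	2o26		Q	R	L. salmonis	PyR2	beyond	5b	B78
3	9	1	S989/2p55P	989	2p55		S	P	Aedes aegypti	IIP1-P2	beyond	5c, 2a,c	B60
3	9	2	V1016/2i18G	1016	2i18		V	G	Aedes aegypti	PyR1	PyR1	5c, 2a,c	B60
3	10	1	A1101T	1101			A	T	Plutella xylostella	II/III	linker/other		B46
3	10	2	P1879S	1879		CTD	P	S	Plutella xylostella	III/IV	linker/other		B46
3	11	1	A1410/3k10V	1410	3k10		A	V	Drosophila melanogaster	PyR1	beyond	6a	B76
3	12	1	A1494/3p47V	1494	3p47		A	V	Drosophila melanogaster	PyR1	beyond	6b	B76
3	13	1	M1524/3i3I	1524	3i3		M	I	Drosophila melanogaster	PyR1	beyond	6c	B76
3	14	1	F1528/3i7L	1528	3i7		F	L	Varroa destructor	PyR1	beyond	6d	B79
3	14	2	M1823/4i3I	1823	4i3		M	I	Varroa destructor	IVS6	beyond	6d	B79
3	15	1	D1549/3i28V	1549	3i28		D	V	Helicoverpa armigera	PyR1, PyR2	beyond	6e	B80
3	15	2	E1553/3i32G	1553	3i32		E	G	Helicoverpa armigera	PyR1, PyR2	beyond	6e	B80
3	16	1	A1215D	1215			A	D	Tetranychus urticae	II/III	linker/other		B81
3	16	2	F1538/3i17I	1538	3i17		F	I	Tetranychus urticae	PyR1	PyR1		B81
3	17	1	W1594R	1594			W	R	Culex quinquefasciatus	N-end of IVS0	beyond		B75
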