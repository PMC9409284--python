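table	row	comp	raw	native	universal	region	wt	sub	species	location	site	figures	ref
1	1	1	V253/1k11F	253	1k11		V	F	Aedes aegypti	PyR2	PyR2	2b,d	B16
1	2	1	T267/1o13A	267	1o13		T	A	Plant hopper	PyR2	PyR2	2b,d	B17
1	3	1	V410/1i19M	410	1i19		V	M	Helicoverpa zea	PyR2	PyR2	2b,d	B32
1	4	1	V410/1i19L	410	1i19		V	L	Cimex luctularis	PyR2	PyR2	2b,d	B33
1	5	1	V410/1i19G/A	410	1i19		V	G/A	Helicoverpa zea	PyR2	PyR2	2b,d	B32
1	6	1	V1010/2i12L	1010	2i12		V	L	Anopheles culicifacies	PyR2	PyR2	2b,d	B34
1	6	2	L1014/2i16S	1014	2i16		L	S	Anopheles culicifacies	PyR2	PyR2	2b,d	B34
1	7	1	I1011/2i13M	1011	2i13		I	M	Aedes aegypti	PyR2	PyR2	2b,d	B35
1	8	1	I1011/2i13V	1011	2i13		I	V	Aedes aegypti	PyR2	PyR2	2b,d	B36
1	9	1	N1013/2i15S	1013	2i15		N	S	Anopheles sinensis	PyR2	PyR2	2b,d	B37
1	10	1	L1014/2i16F	1014	2i16		L	F	Anopheles gambiae	PyR2	PyR2	2b,d	B38
1	11	1	L1014/2i16S	1014	2i16		L	S	Anopheles arabiensis	PyR2	PyR2	2b,d	B39
1	12	1	L1014/2i16H	1014	2i16		L	H	Helicoverpa zea	PyR2	PyR2	2b,d	B32
1	13	1	L1014/2i16C	1014	2i16		L	C	Anopheles sinensis	PyR2	PyR2	2b,d	B40
1	14	1	L1014/2i16W	1014	2i16		L	W	Anopheles sinensis	PyR2	PyR2	2b,d	B37
1	15	1	L1014/2i16F	1014	2i16		L	F	Myzus persicae	PyR2	PyR2	2b,d	B41
1	15	2	F979S	979			F	S	Myzus persicae	IIP1	beyond	2b,d	B41
1	16	1	L1014/2i16F	1014	2i16		L	F	Anopheles gambiae	PyR2	PyR2	2b,d	B42
1	16	2	N1575Y	1575			N	Y	Anopheles gambiae	III-IV	linker/other	2b,d	B42
1	17	1	L1014/2i16F	1014	2i16		L	F	Blattella germanica	PyR2	PyR2	2b,d	B43
1	17	2	E435K	435			E	K	Blattella germanica		beyond	2b,d	B43
1	17	3	C785R	785			C	R	Blattella germanica		linker/other	2b,d	B43
1	18	1	M918/2k11T	918	2k11		M	T	Haematobia i. irritans	PyR1	PyR1	1c, 4a,b,d	B44
1	18	2	L1014/2i16F	1014	2i16		L	F	Haematobia i. irritans	PyR2	PyR2	1c, 4a,b,d	B44
1	19	1	M918/2k11L	918	2k11		M	L	Thrips tabaci	PyR1	PyR1	1c, 2a	B45
1	19	2	V1010/2i12A	1010	2i12		V	A	Thrips tabaci	PyR2	PyR2	1c, 2a	B45
1	20	1	M918/2k11I	918	2k11		M	I	Plutella xylostella	PyR1	PyR1	1c, 2a,b,d	B46
1	20	2	L1014/2i16F	1014	2i16		L	F	Plutella xylostella	PyR2	PyR2	1c, 2a,b,d	B46
1	21	1	T929/2o10I	929	2o10		T	I	Frankliniella occidentalis	PyR1	PyR1	1c, 2a,b,d	B47
1	21	2	L1014/2i16F	1014	2i16		L	F	Frankliniella occidentalis	PyR2	PyR2	1c, 2a,b,d	B47
1	22	1	T929/2o10I	929	2o10		T	I	Plutella xylostella	PyR1	PyR1	1c, 2a,b,d	B48
1	22	2	L1014/2i16F	1014	2i16		L	F	Plutella xylostella	PyR2	PyR2	1c, 2a,b,d	B48
1	23	1	T929/2o10C	929	2o10		T	C	Frankliniella occidentalis	PyR1	PyR1	1c, 2a	B47
1	23	2	L1014/2i16F	1014	2i16		L	F	Frankliniella occidentalis	PyR2	PyR2	1c, 2a	B47
1	24	1	T929/2o10V	929	2o10		T	V	Ctenocephalides felis	PyR1	PyR1	1c, 2a	B49
1	24	2	L1014/2i16F	1014	2i16		L	F	Ctenocephalides felis	PyR2	PyR2	1c, 2a	B49
1	25	1	T929/2o10N	929	2o10		T	N	L. decemlineata	PyR1	PyR1	1c, 2a,b,d	B50
1	25	2	L1014/2i16F	1014	2i16		L	F	L. decemlineata	PyR2	PyR2	1c, 2a,b,d	B50
1	26	1	F979/2p44S	979	2p44		F	S	Myzus persicae	PyR1	PyR1	1c, 2a,b,d	B41
1	26	2	L1014/2i16F	1014	2i16		L	F	Myzus persicae	PyR2	PyR2	1c, 2a,b,d	B41
1	27	1	M918/2k11T	918	2k11		M	T	Aphis gossypii	PyR1	PyR1	1c, 2a	B51
1	28	1	M918/2k11L	918	2k11		M	L	Aphis gossypii	PyR1	PyR1	1c, 2a	B52
1	29	1	M918/2k11L	918	2k11		M	L	Trialeurodesvaporariorum	PyR1	PyR1	1c, 2a	B53
1	29	2	L925/2o6I	925	2o6		L	I	Trialeurodesvaporariorum	PyR1	PyR1	1c, 2a	B53
1	30	1	M918/2k11V	918	2k11		M	V	Bemisia tabaci	PyR1	PyR1	1c, 2a	B54
1	31	1	L925/2o6I	925	2o6		L	I	Bemisia tabaci	PyR1	PyR1	1c, 2a	B54
1	32	1	L925/2o6V	925	2o6		L	V	Varroa destructor	PyR1	PyR1	1c, 2a	B55
1	33	1	T929/2o10I	929	2o10		T	I	Thrips tabaci	PyR1	PyR1	1c, 2a	B56
1	34	1	T929/2o10I	929	2o10		T	I	P. humanus capitis	PyR1	PyR1	1c, 2a	B57
1	34	2	L932/2o13F	932	2o13		L	F	P. humanus capitis	PyR1	PyR1	1c, 2a	B57
1	35	1	T929/2o10I	929	2o10		T	I	P. humanus capitis	PyR1	PyR1	1c, 2a	B58
1	35	2	M827I	827		IIS1-S2	M	I	P. humanus capitis	VSM2	beyond	1c, 2a	B58
1	36	1	T929/2o10C	929	2o10		T	C	Frankliniella occidentalis	PyR1	PyR1	1c, 2a	B47
1	37	1	T929/2o10V	929	2o10		T	V	Bemisia tabaci	PyR1	PyR1	1c, 2a	B59
1	38	1	L932/2o13F	932	2o13		L	F	P. humanus capitis	PyR1	PyR1	1c, 2a	B58
1	38	2	M827I	827		IIS1-S2	M	I	P. humanus capitis	VSM2	beyond	1c, 2a	B58
1	39	1	I936/2o17V	936	2o17		I	V	Helicoverpa zea	PyR1	PyR1	1c, 2a	B32
1	40	1	L982/2p47W	982	2p47		L	W	Aedes aegypti	PyR1	PyR1	1c	B35
1	41	1	V1016/2i18G	1016	2i18		V	G	Aedes aegypti	PyR1	PyR1	2a,c	B35
1	42	1	V1016/2i18G	1016	2i18		V	G	Aedes aegypti	PyR1	PyR1	2a,c	B60
1	42	2	S989/2p55P	989	2p55		S	P	Aedes aegypti		beyond	2a,c	B60
1	43	1	V1016/2i18G	1016	2i18		V	G	Aedes aegypti	PyR1	PyR1	2a,c	B61
1	43	2	D1763Y	1763			D	Y	Aedes aegypti		beyond	2a,c	B61
1	44	1	V1016/2i18I	1016	2i18		V	I	Aedes aegypti	PyR1	PyR1	2a,c	B36
1	45	1	F1020/2i22S	1020	2i22		F	S	Blattella germanica	PyR1	PyR1	2a	B62
1	46	1	L1024/2i26V	1024	2i26		L	V	Tetranychus urticae	PyR1	PyR1	1c, S5b	B63
1	47	1	F1534/3i13C	1534	3i13		F	C	Aedes aegypti	PyR1	PyR1	1c, 2a	B64
1	48	1	F1534/3i13L	1534	3i13		F	L	Aedes aegypti	PyR1	PyR1	1c, 2a	B65
1	49	1	F1537/3i16L	1537	3i16		F	L	Dermanyssus gallinae	PyR1	PyR1	1c	B66
1	50	1	F1538/3i17I	1538	3i17		F	I	Rhipicephalus microplus	PyR1	PyR1	1c, 2a	B67
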