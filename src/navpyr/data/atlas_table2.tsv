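table	row	comp	raw	native	universal	region	wt	sub	species	location	site	figures	ref
2	1	1	L260/1o6A	260	1o6		L	A	AaNav1-1	PyR2	PyR2	2b,d	B12
2	2	1	I264/1o10C	264	1o10		I	C	AaNav1-1	PyR2	PyR2	2b,d	B11
2	3	1	I413/1i22A	413	1i22		I	A	AaNav1-1	PyR2	PyR2	2b,d	B12
2	4	1	M918/2k11T	918	2k11		M	T	DmNav	PyR1	PyR1	4c,2a,c	B68
2	5	1	V922/2o3I	922	2o3		V	I	BiNav1-1	PyR1	PyR1	6c	B15
2	6	1	L925/2o6I	925	2o6		L	I	DmNav	PyR1	PyR1	1c	B68
2	7	1	T929/2o10I	929	2o10		T	I	DmNav	PyR1	PyR1	1c,2a	B68
2	8	1	L932/2o13F	932	2o13		L	F	DmNav	PyR1	PyR1	1c,2a	B68
2	9	1	C933/2o14A	933	2o14		C	A	DmNav	PyR1	PyR1	1c,2a	B68
2	10	1	I936/2o17V	936	2o17		I	V	DmNav	PyR1	PyR1	1c,2a	B68
2	11	1	N1013/2i15S	1013	2i15		N	S	AaNav1-1	PyR2	PyR2	2b,d	B12
2	12	1	F1020/2i22S	1020	2i22		F	S	AaNav1-1	PyR1	PyR1	1c,2a	B12
2	13	1	L1023/2i25A	1023	2i25		L	A	AaNav1-1	PyR1	PyR1	2a	B12
2	14	1	L1024/2i26A	1024	2i26		L	A	AaNav1-1	PyR1	PyR1	1c	B12
2	15	1	F1526/3i5L	1526	3i5		F	L	BiNav1-1	PyR1 (tau-FVL)	PyR1	6c	B15
2	16	1	V1529/3i8A	1529	3i8		V	A	BiNav1-1	PyR1 (tau-FVL)	PyR1	1c,2a	B15
2	17	1	I1533/3i12A	1533	3i12		I	A	BgNav1-1a	PyR1	PyR1	1c,2a	B69
2	18	1	F1537/3i16A	1537	3i16		F	A	BgNav1-1a	PyR1	PyR1	2a	B69
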