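type	eps	sigma	charge	element
N	0.170	3.10	-0.35	N
CA	0.080	3.40	0.10	C
C	0.105	3.40	0.45	C
O	0.210	2.90	-0.45	O
CH2	0.118	3.50	0.00	C
CH3	0.175	3.50	0.00	C
CAR	0.110	3.40	0.00	C
OH	0.170	2.95	-0.38	O
OD	0.210	2.90	-0.55	O
CD	0.105	3.40	0.25	C
S	0.250	3.40	-0.12	S
NR	0.170	3.10	0.35	N
CZ	0.105	3.40	0.30	C
CE	0.175	3.50	0.00	C
CV	0.105	3.30	0.00	C
CL	0.300	3.30	-0.08	CL
BR	0.400	3.50	-0.05	BR
OE	0.170	2.90	-0.40	O
OC	0.210	2.90	-0.45	O
CO	0.105	3.40	0.55	C
CN	0.150	3.40	0.30	C
NC	0.170	3.10	-0.40	N
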