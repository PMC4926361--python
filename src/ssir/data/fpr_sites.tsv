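R1	R2	R3	R4
A	A	A	A
B	B	B	B
C	C	C	C
D	D	D	D
E	E	E	E
	F	F	F
	G	G	G
	H	H	H
		I	I
			J
			K
			L
			M
			N
			O
			P
			Q
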