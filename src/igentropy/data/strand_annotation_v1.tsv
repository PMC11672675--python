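# igentropy Aho-grid annotation, version v1 (approximate)
chain	kind	label	aho_start	aho_end
L	strand	A	2	7
L	strand	A'	9	14
L	strand	B	16	23
L	strand	C	43	49
L	strand	C'	51	57
L	strand	C''	75	80
L	strand	D	84	90
L	strand	E	93	99
L	strand	F	101	106
L	strand	G	139	146
H	strand	A	2	7
H	strand	A''	9	14
H	strand	B	16	23
H	strand	C	43	50
H	strand	C'	52	56
H	strand	C''	80	85
H	strand	D	88	94
H	strand	E	97	101
H	strand	F	102	106
H	strand	G	139	147
L	core	core	16	23
L	core	core	43	57
L	core	core	98	106
H	core	core	16	23
H	core	core	43	56
H	core	core	97	106
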