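# approximate S. cerevisiae proteome amino-acid composition (percent); default neutral reference
amino_acid	weight
A	5.5
C	1.3
D	5.8
E	6.5
F	4.5
G	5.0
H	2.2
I	6.6
K	7.3
L	9.6
M	2.1
N	6.1
P	4.4
Q	3.9
R	4.4
S	9.0
T	5.9
V	5.6
W	1.0
Y	3.4
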