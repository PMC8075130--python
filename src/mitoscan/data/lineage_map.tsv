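prefix	lineage
L0	L0
L1	L1
L2	L2
L3	L3
L4	L4
L5	L5
L6	L6
M	M
N	N
R	R
H	H
V	H
U	U
K	U
J	JT
T	JT
A	N
B	R
C	M
D	M
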