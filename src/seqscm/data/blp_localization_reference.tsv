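# Amino-acid compositions (percent) of bioluminescent proteins, integral
# membrane proteins, and nuclear proteins, for localization analysis.
residue	comp_blp	comp_membrane	comp_nuclear
A	7.12	8.1	8.3
C	2.09	2.0	1.6
D	5.82	3.8	4.7
E	6.25	4.6	6.5
F	4.58	5.6	2.7
G	7.53	7.0	6.3
H	2.75	2.0	2.1
I	5.6	6.7	3.7
K	5.14	4.4	7.9
L	9.31	11.0	7.4
M	2.42	2.8	2.3
N	4.23	3.7	3.7
P	4.99	4.7	6.9
Q	3.7	3.1	4.7
R	4.96	4.6	8.7
S	6.61	7.3	8.8
T	5.51	5.6	5.1
V	6.6	7.7	5.3
W	1.22	1.8	0.7
Y	3.56	3.3	2.4
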