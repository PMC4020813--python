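# Reference amino-acid propensity scores for the luciferase-vs-
# fluorescent-protein scoring card, with the published class
# compositions (percent) of the luciferase and FP sets and the
# composition of integral membrane proteins.
residue	score	comp_pos	comp_neg	comp_membrane
A	726.425	8.25	5.04	8.1
C	598.4	1.58	1.36	2.0
D	574.025	5.79	6.25	3.8
E	569.0	6.34	6.85	4.6
F	591.925	4.82	4.89	5.6
G	490.975	6.84	9.31	7.0
H	516.425	2.49	4.22	2.0
I	646.125	6.05	4.78	6.7
K	476.225	4.83	7.69	4.4
L	729.9	10.41	7.17	11.0
M	555.8	2.47	3.31	2.8
N	575.95	3.85	4.22	3.7
P	579.1	4.48	4.83	4.7
Q	610.95	3.55	3.14	3.1
R	674.05	5.64	3.75	4.6
S	650.575	6.61	5.23	7.3
T	535.05	4.84	6.21	5.6
V	594.625	6.52	6.45	7.7
W	604.525	1.24	0.98	1.8
Y	549.95	3.38	4.33	3.3
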