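# Reference amino-acid propensity scores for the bioluminescent-protein
# (BLP vs non-BLP) scoring card, with the published class amino-acid
# compositions (percent) of the BLP and non-BLP training sets.
residue	score	comp_pos	comp_neg
A	359.75	7.12	8.15
C	572.85	2.09	1.28
D	498.1	5.82	5.55
E	404.075	6.25	6.79
F	548.075	4.58	3.9
G	573.025	7.53	6.49
H	534.45	2.75	2.33
I	456.525	5.6	5.66
K	336.275	5.14	5.8
L	426.7	9.31	9.7
M	483.15	2.42	2.27
N	451.125	4.23	4.21
P	472.95	4.99	4.91
Q	435.025	3.7	4.03
R	384.875	4.96	5.51
S	368.5	6.61	7.27
T	452.75	5.51	5.4
V	477.775	6.6	6.45
W	434.575	1.22	1.27
Y	508.75	3.56	3.05
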