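# Per-residue physicochemical property scales (AAindex-derived) used to
# characterize bioluminescent proteins: transfer free energy from the
# protein interior to the surface, average transmembrane-region
# preference, structure-derived hydrophobicity, and amino-acid
# composition of nuclear proteins.
residue	transfer_free_energy	membrane_preference	hydrophobicity_scale	nuclear_composition
A	0.3	1.26	0.2	8.3
C	0.9	1.6	1.9	1.6
D	-0.6	0.27	-1.4	4.7
E	-0.7	0.23	-1.3	6.5
F	0.5	1.46	1.0	2.7
G	0.3	1.08	-0.1	6.3
H	-0.1	1.0	0.4	2.1
I	0.7	1.44	1.4	3.7
K	-1.8	0.33	-1.6	7.9
L	0.5	1.36	0.5	7.4
M	0.4	1.52	0.5	2.3
N	-0.5	0.59	-0.5	3.7
P	-0.3	0.54	-1.0	6.9
Q	-0.7	0.39	-1.1	4.7
R	-1.4	0.38	-0.7	8.7
S	-0.1	0.98	-0.7	8.8
T	-0.2	1.01	-0.4	5.1
V	0.6	1.33	0.7	5.3
W	0.3	1.06	1.6	0.7
Y	-0.4	0.89	0.5	2.4
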