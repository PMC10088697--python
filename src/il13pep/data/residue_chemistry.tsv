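# Per-residue (amino acid minus water) elemental composition and covalent-bond
# summary for the 20 canonical amino acids, derived from the standard residue
# molecular formulas and side-chain structures.
# rings: number of rings (Pro 1, Phe 1, Tyr 1, His 1, Trp 2).
# double_bonds: backbone C=O plus side-chain double bonds (amide/carboxylate
# C=O, guanidinium C=N, aromatic-ring double bonds: benzene 3, imidazole 2,
# indole 4).
# Derived by the encoder: total bonds = atoms - 1 + rings; single = total - double;
# hydrogen = H-atom count.
residue	C	H	N	O	S	rings	double_bonds
A	3	5	1	1	0	0	1
C	3	5	1	1	1	0	1
D	4	5	1	3	0	0	2
E	5	7	1	3	0	0	2
F	9	9	1	1	0	1	4
G	2	3	1	1	0	0	1
H	6	7	3	1	0	1	3
I	6	11	1	1	0	0	1
K	6	12	2	1	0	0	1
L	6	11	1	1	0	0	1
M	5	9	1	1	1	0	1
N	4	6	2	2	0	0	2
P	5	7	1	1	0	1	1
Q	5	8	2	2	0	0	2
R	6	12	4	1	0	0	2
S	3	5	1	2	0	0	1
T	4	7	1	2	0	0	1
V	5	9	1	1	0	0	1
W	11	10	2	1	0	2	5
Y	9	9	1	2	0	1	4
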