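# Goldman-Engelman-Steitz (GES) hydrophobicity scale.
# Transfer free energy (kcal/mol) for moving a residue in an alpha-helix
# from water into the membrane; positive = hydrophobic.
# Engelman, Steitz & Goldman (1986) Annu Rev Biophys Biophys Chem 15:321-353.
residue	transfer_free_energy
F	3.7
M	3.4
I	3.1
L	2.8
V	2.6
C	2.0
W	1.9
A	1.6
T	1.2
G	1.0
S	0.6
P	-0.2
Y	-0.7
H	-3.0
Q	-4.1
N	-4.8
E	-8.2
K	-8.8
D	-9.2
R	-12.3
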