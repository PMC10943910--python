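# In-chain residue masses (Da); free peptide mass = sum + water (18.01528 avg / 18.010565 mono)
residue	average	monoisotopic
A	71.0788	71.03711
C	103.1388	103.00919
D	115.0886	115.02694
E	129.1155	129.04259
F	147.1766	147.06841
G	57.0519	57.02146
H	137.1411	137.05891
I	113.1594	113.08406
K	128.1741	128.09496
L	113.1594	113.08406
M	131.1926	131.04049
N	114.1038	114.04293
P	97.1167	97.05276
Q	128.1307	128.05858
R	156.1875	156.10111
S	87.0782	87.03203
T	101.1051	101.04768
V	99.1326	99.06841
W	186.2132	186.07931
Y	163.1760	163.06333
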