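# Default ACP-like residue frequency profile: enriched K,R,W,F,L; depleted D,E
# (cationic/hydrophobic character typical of anticancer peptides)
residue	freq
A	0.07
C	0.01
D	0.01
E	0.01
F	0.08
G	0.06
H	0.02
I	0.06
K	0.13
L	0.12
M	0.02
N	0.02
P	0.03
Q	0.02
R	0.11
S	0.04
T	0.03
V	0.06
W	0.06
Y	0.04
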