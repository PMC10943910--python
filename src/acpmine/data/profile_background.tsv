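# Default non-ACP background profile: uniform residue usage
residue	freq
A	0.05
C	0.05
D	0.05
E	0.05
F	0.05
G	0.05
H	0.05
I	0.05
K	0.05
L	0.05
M	0.05
N	0.05
P	0.05
Q	0.05
R	0.05
S	0.05
T	0.05
V	0.05
W	0.05
Y	0.05
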