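# SYNTHETIC antimicrobial-propensity stand-in scale (0..1, higher = more active).
# Hand-built to favour cationic/aromatic/aliphatic residues; NOT the scale of any
# published propensity server. Users may drop in a real scale file of this format.
residue	value
A	0.35
C	0.60
D	0.05
E	0.05
F	0.70
G	0.40
H	0.50
I	0.55
K	0.75
L	0.60
M	0.45
N	0.25
P	0.25
Q	0.20
R	0.80
S	0.30
T	0.30
V	0.50
W	0.85
Y	0.50
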