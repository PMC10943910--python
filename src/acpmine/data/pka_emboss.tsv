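# EMBOSS ionizable-group pKa set, version 1 (immutable)
group	pka	kind
nterm	8.6	basic
cterm	3.6	acidic
D	3.9	acidic
E	4.1	acidic
C	8.5	acidic
Y	10.1	acidic
H	6.5	basic
K	10.8	basic
R	12.5	basic
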