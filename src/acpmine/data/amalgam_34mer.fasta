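>amalgam_34mer homeodomain-derived 30-mer core with AAEK N-terminal extension
AAEKEFIKYPYPTPLQYQQLATRLKVEKKLVRRW
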