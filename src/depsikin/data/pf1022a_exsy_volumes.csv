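site,A,B,C
A,77.9,1.52,1.55
B,1.59,236,0
C,1.75,0,200
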