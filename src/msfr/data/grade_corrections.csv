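grade,factor
0,1.00
1,1.05
2,1.12
3,1.25
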