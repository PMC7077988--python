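>SYNTH_O O
A [ 197   1   0   1 198 196 195   1 ]
C [   1   1   1 196   1   1   1   2 ]
G [   1   0 198   1   0   1   3   0 ]
T [   1 198   1   2   1   2   1 197 ]
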