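>SYNTH_K K
A [   1   2   1   1  10 196 196   1 196 ]
C [   2   1   1   2 110   1   2   1   2 ]
G [ 196 196 196 196  30   2   1 196   1 ]
T [   1   1   2   1  50   1   1   2   1 ]
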