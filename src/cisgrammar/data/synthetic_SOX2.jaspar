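>SYNTH_S S
A [   1 197   1   0   1   1   0  12 ]
C [ 197   1   1   1   0   1   1 140 ]
G [   1   1   0   1 198   0   1  24 ]
T [   1   1 198 198   1 198 198  24 ]
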