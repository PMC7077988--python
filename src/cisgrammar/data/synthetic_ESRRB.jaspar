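>SYNTH_E E
A [   1   1 197 196   1   1   0   1 195 ]
C [   1 197   1   1   0   1   2 197   2 ]
G [   1   1   1   2 198 197   0   1   2 ]
T [ 197   1   1   1   1   1 198   1   1 ]
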