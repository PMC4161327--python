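>FOXA_CORE FOXA-core
A [  2  2  2  0  2 12  2 ]
C [  2  2  2  0  2  2 12 ]
G [  2 12  2  0  2  2  2 ]
T [ 12  2 12 18 12  2  2 ]
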