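>E2F1_consensus_synthetic
A  [   2   2   2   3   3   2   2   2 ]
C  [   2   2   2  50  50  94   2  94 ]
G  [   2   2   2  50  50   2  94   2 ]
T  [  94  94  94   3   3   2   2   2 ]
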