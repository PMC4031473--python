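>REST_NRSE_consensus_synthetic
A  [   2   2   2  94   2   2  94   2   2  94   2   2   2  94   2  94   2   2   2   2   2 ]
C  [   2   2  94   2   2  94   2  94  94   2  94   2   2   2  94   2   2  94   2  94  94 ]
G  [   2   2   2   2  94   2   2   2   2   2   2  94  94   2   2   2  94   2  94   2   2 ]
T  [  94  94   2   2   2   2   2   2   2   2   2   2   2   2   2   2   2   2   2   2   2 ]
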