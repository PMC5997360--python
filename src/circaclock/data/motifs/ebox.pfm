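>EBOX0001 Ebox-standin (BMAL1-like example matrix, not a database original)
A [  5 85  5  5  5  5 70 ]
C [ 85  5 85  5  5  5 10 ]
G [  5  5  5 85  5 85 10 ]
T [  5  5  5  5 85  5 10 ]
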