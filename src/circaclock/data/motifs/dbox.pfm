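>DBOX0001 Dbox-standin (DBP-like example matrix, not a database original)
A [  5  5 80  5  5  5 85 75 ]
C [  8  5  6  5  5  5  5  8 ]
G [  7  5  8  5 85  5  5  8 ]
T [ 80 85  6 85  5 85  5  9 ]
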