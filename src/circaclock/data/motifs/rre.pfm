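>RRE0001 RRE-standin (ROR-like example matrix, not a database original)
A [ 60 70 80  5  5 85  3  3  3  3 80 ]
C [ 15 10  6  5  5  5  3  3  3 91  6 ]
G [ 15 10  8 85  5  5 91 91  3  3  8 ]
T [ 10 10  6  5 85  5  3  3 91  3  6 ]
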