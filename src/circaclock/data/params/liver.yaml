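# Core-clock model rate constants for the 'liver' fit.
tissue: liver
tau_Bmal1: 4.89
tau_RevErba: 0.66
tau_Per2: 4.0
tau_Cry1: 4.0
tau_Dbp: 3.0
d_Bmal1: 0.58
d_RevErba: 0.61
d_Per2: 0.24
d_Cry1: 0.18
d_Dbp: 0.63
ar1: 4.05
ar4: 1.1
cr2: 1.83
cr3: 33.5
cr4: 6.63
cr5: 0.99
gr2: 80.2
gr3: 0.37
gr4: 0.51
gr5: 1.02
b2: 3.26
ba2: 0.51
b3: 3.69
ba3: 14.78
b4: 1.35
ba4: 1.06
b5: 12.87
ba5: 0.01
f2: 1.23
fa2: 0.19
f3: 11.69
fa3: 0.58
f4: 32.2
fa4: 1.61
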