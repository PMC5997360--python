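# Core-clock model rate constants for the 'all_tissues' fit.
tissue: all_tissues
tau_Bmal1: 6.28
tau_RevErba: 0.56
tau_Per2: 3.95
tau_Cry1: 3.84
tau_Dbp: 3.0
d_Bmal1: 0.39
d_RevErba: 0.58
d_Per2: 0.27
d_Cry1: 0.22
d_Dbp: 0.42
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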