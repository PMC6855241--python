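element	radius
H	1.20
C	1.70
N	1.55
O	1.52
S	1.80
P	1.80
F	1.47
Cl	1.75
Br	1.85
I	1.98
Se	1.90
Na	2.27
K	2.75
Mg	1.73
Ca	2.31
Zn	1.39
Fe	1.80
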