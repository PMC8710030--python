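# Single-bond covalent radii in Angstrom.
# Source: B. Cordero et al., "Covalent radii revisited", Dalton Trans. 2008,
# 2832-2838 (sp3 value for carbon; low-spin values where two are given).
# Users may override any entry via RadiiTable.with_overrides().
# element	radius_angstrom
H	0.31
He	0.28
Li	1.28
Be	0.96
B	0.84
C	0.76
N	0.71
O	0.66
F	0.57
Ne	0.58
Na	1.66
Mg	1.41
Al	1.21
Si	1.11
P	1.07
S	1.05
Cl	1.02
Ar	1.06
K	2.03
Ca	1.76
Fe	1.32
Zn	1.22
Br	1.20
I	1.39
X	0.00
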