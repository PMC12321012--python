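# van der Waals radii (Å), per element.
# Source: S. Alvarez, "A cartography of the van der Waals territories",
# Dalton Trans. 42 (2013) 8617-8636. Crystallographic vdW radii.
# Columns: element  radius_A
H   1.20
He  1.43
Li  2.12
Be  1.98
B   1.91
C   1.77
N   1.66
O   1.50
F   1.46
Ne  1.58
Na  2.50
Mg  2.51
Al  2.25
Si  2.19
P   1.90
S   1.89
Cl  1.82
Ar  1.83
K   2.73
Ca  2.62
Sc  2.58
Ti  2.46
V   2.42
Cr  2.45
Mn  2.45
Fe  2.44
Co  2.40
Ni  2.40
Cu  2.38
Zn  2.39
Ga  2.32
Ge  2.29
As  1.88
Se  1.82
Br  1.86
Kr  2.25
Rb  3.21
Sr  2.84
Y   2.75
Zr  2.52
Nb  2.56
Mo  2.45
Ru  2.46
Rh  2.44
Pd  2.15
Ag  2.53
Cd  2.49
In  2.43
Sn  2.42
Sb  2.47
Te  1.99
I   2.04
Xe  2.06
Cs  3.48
Ba  3.03
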