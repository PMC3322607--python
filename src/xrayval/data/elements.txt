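# Element properties used across the toolkit.
# columns: symbol  electrons  vdw_radius_angstrom
# vdW radii follow Bondi-style consensus values; electrons are atomic numbers
# (neutral-atom scattering weight under the flat-form-factor convention).
H   1   1.20
C   6   1.70
N   7   1.55
O   8   1.52
F   9   1.47
NA  11  2.27
MG  12  1.73
P   15  1.80
S   16  1.80
CL  17  1.75
K   19  2.75
CA  20  2.31
MN  25  2.05
FE  26  2.05
CO  27  2.00
NI  28  1.63
CU  29  1.40
ZN  30  1.39
SE  34  1.90
BR  35  1.85
I   53  1.98
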