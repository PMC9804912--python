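# Eisenberg normalized consensus hydrophobicity scale (dimensionless).
# One row per canonical amino acid: one-letter code <TAB> value.
aa	hydrophobicity
I	0.73
F	0.61
V	0.54
L	0.53
W	0.37
M	0.26
A	0.25
G	0.16
C	0.04
Y	0.02
P	-0.07
T	-0.18
S	-0.26
H	-0.40
E	-0.62
N	-0.64
Q	-0.69
D	-0.72
K	-1.10
R	-1.76
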