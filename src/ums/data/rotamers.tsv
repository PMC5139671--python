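# Coarse backbone-independent rotamer library.
# Columns: aa	chi1	chi2	chi3	chi4	probability
# Empty chi fields mean the amino acid has fewer torsional degrees of freedom.
# Chi angles (degrees) and probabilities are rounded, field-typical values.
A					1.0
G					1.0
S	-65				0.42
S	62				0.33
S	180				0.25
C	-65				0.55
C	62				0.23
C	180				0.22
T	62				0.49
T	-60				0.43
T	180				0.08
V	175				0.73
V	-60				0.20
V	62				0.07
P	30	-35			0.55
P	-25	35			0.45
L	-65	175			0.59
L	180	65			0.29
L	-85	65			0.07
L	180	180			0.05
I	-65	170			0.60
I	-57	-60			0.15
I	62	170			0.15
I	180	170			0.10
D	-70	-15			0.51
D	180	0			0.30
D	62	-10			0.19
N	-65	-20			0.47
N	180	-60			0.28
N	62	-75			0.25
H	-65	-70			0.33
H	180	-80			0.30
H	62	-75			0.22
H	-65	165			0.15
F	-65	90			0.44
F	180	80			0.33
F	62	90			0.13
F	-85	-30			0.10
Y	-65	90			0.44
Y	180	80			0.33
Y	62	90			0.13
Y	-85	-30			0.10
W	-65	95			0.32
W	180	-105			0.28
W	-65	-90			0.20
W	62	-90			0.12
W	180	75			0.08
M	-65	180	75		0.25
M	-65	-65	-70		0.25
M	180	180	75		0.20
M	-65	180	180		0.15
M	62	180	75		0.15
E	-65	180	-10		0.42
E	180	180	0		0.30
E	-65	-65	-40		0.17
E	62	180	-10		0.11
Q	-65	180	-25		0.41
Q	180	180	10		0.28
Q	-65	-65	-45		0.20
Q	62	180	20		0.11
K	-65	180	180	180	0.40
K	180	180	180	180	0.30
K	-65	-65	180	180	0.15
K	62	180	180	180	0.15
R	-65	180	180	180	0.37
R	180	180	180	180	0.28
R	-65	-65	180	180	0.20
R	62	180	180	65	0.15
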