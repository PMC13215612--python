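# token	monoisotopic_mass	modification
<pad>	0.0	sentinel
<unk>	0.0	sentinel
G	57.02146372
A	71.03711379
S	87.03202841
P	97.05276385
V	99.06841391
T	101.04767847
C	160.03064820	carbamidomethyl (fixed, +57.02146)
L	113.08406398
I	113.08406398
N	114.04292744
D	115.02694302
Q	128.05857750
K	128.09496302
E	129.04259309
M	131.04048509
H	137.05891186
F	147.06841391
R	156.10111102
Y	163.06332853
W	186.07931295
M(ox)	147.03539971	oxidation (variable, +15.99491)
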