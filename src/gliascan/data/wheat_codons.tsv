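residue	codon
A	GCC
C	TGC
D	GAC
E	GAG
F	TTC
G	GGC
H	CAC
I	ATC
K	AAG
L	CTC
M	ATG
N	AAC
P	CCA
Q	CAA
R	AGG
S	TCC
T	ACC
V	GTC
W	TGG
Y	TAC
*	TAA
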