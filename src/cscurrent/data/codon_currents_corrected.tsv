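# codon Chern-Simons currents, variant=corrected
codon	amino_acid_3	amino_acid_1	is_stop	current
UUU	Phe	F	0	0.7071
UUC	Phe	F	0	0.5000
UUA	Leu	L	0	0.3717
UUG	Leu	L	0	0.2887
UCU	Ser	S	0	0.0534
UCC	Ser	S	0	0.0495
UCA	Ser	S	0	0.0460
UCG	Ser	S	0	0.0429
UAU	Tyr	Y	0	0.0214
UAC	Tyr	Y	0	0.0205
UAA	Ter	*	1	0.0197
UAG	Ter	*	1	0.0189
UGU	Cys	C	0	0.0122
UGC	Cys	C	0	0.0118
UGA	Ter	*	1	0.0115
UGG	Trp	W	0	0.0112
CUU	Leu	L	0	0.2319
CUC	Leu	L	0	0.1913
CUA	Leu	L	0	0.1612
CUG	Leu	L	0	0.1382
CCU	Pro	P	0	0.0402
CCC	Pro	P	0	0.0377
CCA	Pro	P	0	0.0354
CCG	Pro	P	0	0.0334
CAU	His	H	0	0.0182
CAC	His	H	0	0.0175
CAA	Gln	Q	0	0.0169
CAG	Gln	Q	0	0.0163
CGU	Arg	R	0	0.0109
CGC	Arg	R	0	0.0106
CGA	Arg	R	0	0.0103
CGG	Arg	R	0	0.0101
AUU	Ile	I	0	0.1201
AUC	Ile	I	0	0.1057
AUA	Ile	I	0	0.0939
AUG	Met	M	0	0.0841
ACU	Thr	T	0	0.0316
ACC	Thr	T	0	0.0299
ACA	Thr	T	0	0.0284
ACG	Thr	T	0	0.0270
AAU	Asn	N	0	0.0157
AAC	Asn	N	0	0.0152
AAA	Lys	K	0	0.0147
AAG	Lys	K	0	0.0142
AGU	Ser	S	0	0.0098
AGC	Ser	S	0	0.0096
AGA	Arg	R	0	0.0093
AGG	Arg	R	0	0.0091
GUU	Val	V	0	0.0759
GUC	Val	V	0	0.0690
GUA	Val	V	0	0.0630
GUG	Val	V	0	0.0579
GCU	Ala	A	0	0.0257
GCC	Ala	A	0	0.0245
GCA	Ala	A	0	0.0234
GCG	Ala	A	0	0.0224
GAU	Asp	D	0	0.0138
GAC	Asp	D	0	0.0134
GAA	Glu	E	0	0.0129
GAG	Glu	E	0	0.0126
GGU	Gly	G	0	0.0089
GGC	Gly	G	0	0.0087
GGA	Gly	G	0	0.0085
GGG	Gly	G	0	0.0083
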