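# E. coli K-12 codon usage fractions (per amino acid), standard public values.
# Columns: codon, fraction within synonymous family, amino acid (one letter, * = stop).
codon	fraction	amino_acid
GCG	0.36	A
GCC	0.27	A
GCA	0.21	A
GCT	0.16	A
CGC	0.40	R
CGT	0.38	R
CGG	0.10	R
CGA	0.06	R
AGA	0.04	R
AGG	0.02	R
AAC	0.55	N
AAT	0.45	N
GAT	0.63	D
GAC	0.37	D
TGC	0.56	C
TGT	0.44	C
CAG	0.65	Q
CAA	0.35	Q
GAA	0.69	E
GAG	0.31	E
GGC	0.40	G
GGT	0.34	G
GGG	0.15	G
GGA	0.11	G
CAT	0.57	H
CAC	0.43	H
ATT	0.51	I
ATC	0.42	I
ATA	0.07	I
CTG	0.50	L
TTA	0.13	L
TTG	0.13	L
CTT	0.10	L
CTC	0.10	L
CTA	0.04	L
AAA	0.77	K
AAG	0.23	K
ATG	1.00	M
TTT	0.57	F
TTC	0.43	F
CCG	0.52	P
CCA	0.19	P
CCT	0.16	P
CCC	0.12	P
AGC	0.28	S
TCT	0.15	S
TCC	0.15	S
AGT	0.15	S
TCG	0.15	S
TCA	0.12	S
ACC	0.44	T
ACG	0.27	T
ACT	0.17	T
ACA	0.13	T
TGG	1.00	W
TAT	0.57	Y
TAC	0.43	Y
GTG	0.37	V
GTT	0.26	V
GTC	0.22	V
GTA	0.15	V
TAA	0.64	*
TAG	0.07	*
TGA	0.29	*
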