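# SYNTHETIC stand-in table: per-codon decoding tRNA abundances (arbitrary units).
# Values are seeded random draws, independent of codon usage; they are NOT measured data.
codon	abundance
AAA	0.296
AAC	0.647
AAG	1.375
AAT	0.344
ACA	6.59
ACC	0.84
ACG	6.649
ACT	1.822
AGA	1.101
AGC	4.068
AGG	2.519
AGT	0.501
ATA	0.392
ATC	6.491
ATG	1.072
ATT	2.719
CAA	0.526
CAC	0.458
CAG	0.35
CAT	0.297
CCA	0.713
CCC	0.22
CCG	1.189
CCT	1.896
CGA	0.529
CGC	1.543
CGG	3.475
CGT	4.04
CTA	0.299
CTC	0.522
CTG	2.714
CTT	0.327
GAA	5.244
GAC	1.518
GAG	0.685
GAT	1.61
GCA	3.24
GCC	0.427
GCG	0.761
GCT	0.481
GGA	0.405
GGC	1.594
GGG	1.541
GGT	0.875
GTA	7.895
GTC	3.634
GTG	0.723
GTT	1.069
TAC	2.212
TAT	0.939
TCA	6.133
TCC	2.491
TCG	0.355
TCT	1.777
TGC	3.492
TGG	3.563
TGT	0.478
TTA	1.314
TTC	6.385
TTG	0.723
TTT	1.137
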