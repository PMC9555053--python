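# SYNTHETIC stand-in table: averaged A-site ribosome pause value per codon (arbitrary units).
# Values are seeded random draws, independent of codon usage; they are NOT measured data.
codon	pause
AAA	1.743
AAC	1.899
AAG	0.647
AAT	0.606
ACA	1.489
ACC	2.251
ACG	3.662
ACT	0.637
AGA	1.157
AGC	1.194
AGG	0.805
AGT	3.648
ATA	0.522
ATC	2.643
ATG	1.865
ATT	2.244
CAA	1.873
CAC	0.848
CAG	2.863
CAT	3.219
CCA	0.733
CCC	3.794
CCG	1.674
CCT	0.582
CGA	2.716
CGC	2.025
CGG	2.165
CGT	3.976
CTA	0.753
CTC	1.189
CTG	2.728
CTT	0.745
GAA	0.529
GAC	2.152
GAG	0.507
GAT	0.785
GCA	3.623
GCC	2.44
GCG	1.791
GCT	2.219
GGA	2.397
GGC	1.028
GGG	3.709
GGT	0.973
GTA	3.022
GTC	1.888
GTG	2.609
GTT	3.987
TAA	3.003
TAC	1.471
TAG	2.654
TAT	3.619
TCA	3.262
TCC	0.561
TCG	1.209
TCT	0.582
TGA	3.94
TGC	1.111
TGG	1.365
TGT	0.817
TTA	2.64
TTC	0.964
TTG	2.147
TTT	1.724
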