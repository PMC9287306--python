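# Synthetic CSC-style stability weight table (seeded stand-in, not
# published regression coefficients). Higher weight = more stabilizing.
#species=xenopus
#intercept=0.0
AAA	-1.280151
AAC	0.661260
AAG	-0.254785
AAT	1.125934
ACA	0.903059
ACC	0.382242
ACG	1.314070
ACT	1.144920
AGA	-0.533359
AGC	-0.827084
AGG	1.460078
AGT	-1.111905
ATA	-0.181917
ATC	-1.292269
ATG	-0.130594
ATT	0.956784
CAA	-0.103974
CAC	1.156762
CAG	0.894112
CAT	-0.380072
CCA	0.171301
CCC	-0.011402
CCG	-1.436607
CCT	0.152271
CGA	-1.495122
CGC	0.208009
CGG	-0.510780
CGT	-0.877404
CTA	-0.294646
CTC	0.434752
CTG	-0.432738
CTT	-0.496572
GAA	0.373882
GAC	0.720307
GAG	1.087391
GAT	-0.578407
GCA	0.731386
GCC	0.343733
GCG	-0.841200
GCT	-1.315029
GGA	-1.321389
GGC	1.465061
GGG	-0.376317
GGT	-0.018761
GTA	0.676546
GTC	0.875619
GTG	0.778222
GTT	-0.666139
TAC	1.320065
TAT	-0.834104
TCA	-0.163362
TCC	1.433688
TCG	1.029003
TCT	-0.273432
TGC	0.834241
TGG	-0.018922
TGT	0.414887
TTA	0.059714
TTC	0.440742
TTG	1.209410
TTT	0.105054
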