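# Synthetic CSC-style stability weight table (seeded stand-in, not
# published regression coefficients). Higher weight = more stabilizing.
#species=zebrafish
#intercept=0.0
AAA	-0.577360
AAC	-0.562288
AAG	0.516465
AAT	-1.408252
ACA	1.298993
ACC	-0.432854
ACG	0.009583
ACT	0.990195
AGA	0.007802
AGC	-1.372424
AGG	-1.008158
AGT	0.753376
ATA	-1.336158
ATC	-0.396128
ATG	1.135796
ATT	0.493377
CAA	-0.052868
CAC	0.086261
CAG	0.746764
CAT	-0.535457
CCA	1.096131
CCC	0.694402
CCG	-1.362280
CCT	-1.131379
CGA	-1.061179
CGC	0.381646
CGG	-1.021764
CGT	-1.110913
CTA	-0.413936
CTC	-0.148369
CTG	-0.462162
CTT	-1.444805
GAA	0.431183
GAC	0.697926
GAG	-0.261240
GAT	-1.220520
GCA	1.351425
GCC	0.090545
GCG	0.607208
GCT	-0.134306
GGA	-0.423440
GGC	-1.325659
GGG	1.433104
GGT	1.140491
GTA	0.280591
GTC	-0.220852
GTG	0.631823
GTT	-0.250957
TAC	-0.139255
TAT	0.751666
TCA	0.073841
TCC	0.698934
TCG	0.649695
TCT	-1.246683
TGC	0.031380
TGG	1.495810
TGT	0.273730
TTA	-0.591302
TTC	1.412158
TTG	-0.425921
TTT	-1.461829
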