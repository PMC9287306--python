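# Synthetic CSC-style stability weight table (seeded stand-in, not
# published regression coefficients). Higher weight = more stabilizing.
#species=human
#intercept=0.0
AAA	-1.269348
AAC	-1.474417
AAG	0.384364
AAT	0.203126
ACA	0.925194
ACC	-1.397332
ACG	1.088074
ACT	-1.072219
AGA	1.095173
AGC	-1.356899
AGG	-0.529026
AGT	-0.779801
ATA	0.760709
ATC	0.360773
ATG	1.057060
ATT	-0.895822
CAA	0.331210
CAC	-0.240416
CAG	-0.988847
CAT	-1.379716
CCA	-0.420220
CCC	-0.977241
CCG	0.774995
CCT	1.188256
CGA	1.498920
CGC	0.378635
CGG	-1.479694
CGT	1.405059
CTA	-0.360998
CTC	1.462908
CTG	-0.052472
CTT	-0.774826
GAA	-0.528316
GAC	1.304147
GAG	-0.716417
GAT	0.500503
GCA	-0.299676
GCC	-0.726398
GCG	0.328150
GCT	0.043038
GGA	1.017227
GGC	-0.621473
GGG	0.046568
GGT	-1.157616
GTA	-0.819627
GTC	-0.771993
GTG	-0.330291
GTT	-1.255232
TAC	0.177809
TAT	1.489579
TCA	-0.389821
TCC	-1.235239
TCG	1.214714
TCT	-0.583688
TGC	-0.753969
TGG	0.568299
TGT	0.232142
TTA	0.547687
TTC	-0.884845
TTG	1.039041
TTT	1.078106
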