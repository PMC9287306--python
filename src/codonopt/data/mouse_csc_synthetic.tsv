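# Synthetic CSC-style stability weight table (seeded stand-in, not
# published regression coefficients). Higher weight = more stabilizing.
#species=mouse
#intercept=0.0
AAA	-0.721986
AAC	-0.036821
AAG	0.882939
AAT	0.894179
ACA	0.100801
ACC	0.953246
ACG	1.030184
ACT	-1.009836
AGA	-0.335342
AGC	-0.793853
AGG	0.997184
AGT	-1.190102
ATA	1.235904
ATC	0.073309
ATG	1.155331
ATT	-0.304594
CAA	-1.402578
CAC	1.361812
CAG	0.861944
CAT	0.199884
CCA	1.314312
CCC	-1.069105
CCG	-1.308519
CCT	-0.785618
CGA	0.206018
CGC	1.385470
CGG	1.044708
CGT	-0.818371
CTA	1.088304
CTC	-0.514237
CTG	-0.680001
CTT	-1.166929
GAA	-0.393105
GAC	0.534888
GAG	-1.062928
GAT	-1.384663
GCA	-0.186744
GCC	-1.217565
GCG	-1.267726
GCT	1.106547
GGA	-1.125896
GGC	-0.359791
GGG	1.104261
GGT	-0.886832
GTA	-1.380697
GTC	-0.966856
GTG	1.280341
GTT	1.257295
TAC	1.223715
TAT	0.627255
TCA	-1.315801
TCC	0.047499
TCG	0.830592
TCT	-1.256477
TGC	1.124053
TGG	-0.648216
TGT	-0.267351
TTA	-0.341949
TTC	-0.546693
TTG	-0.459020
TTT	0.343177
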