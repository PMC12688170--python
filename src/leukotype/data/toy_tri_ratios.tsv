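context	ratio
ACA	0.9824
ACC	1.1832
ACG	1.0293
ACT	1.3312
CCA	1.4935
CCC	1.0096
CCG	1.5942
CCT	1.001
GCA	1.1879
GCC	0.6354
GCG	0.7502
GCT	1.3936
TCA	0.6358
TCC	1.2334
TCG	0.7866
TCT	0.6962
ATA	0.8374
ATC	0.6155
ATG	1.6745
ATT	0.8029
CTA	0.8579
CTC	1.2589
CTG	0.9461
CTT	1.7387
GTA	0.6064
GTC	0.9137
GTG	0.8411
GTT	1.0281
TTA	1.4241
TTC	1.191
TTG	1.5278
TTT	1.4714
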