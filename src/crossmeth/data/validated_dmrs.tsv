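# Validated cross-species brain DMRs: per-sample promoter methylation means,
# 3 humans (H1-H3) vs 3 rhesus macaques (M1-M3), transcribed from the published
# study's primary validation table. printed_* columns are the values as printed
# there (differences/p computed by the original authors on unrounded data).
# PCR regions are 1-based inclusive browser coordinates (hg18 / rheMac2).
dmr_id	gene	region_human	region_rhesus	H1	H2	H3	M1	M2	M3	printed_difference	printed_p
143	RNF32	chr7:156125452-156125599	chr3:193770671-193770806	0.287	0.260	0.310	0.953	0.903	0.905	-0.647	8.2E-06
103	K6IRS2	chr12:51281338-51281660	chr11:49678948-49679270	0.225	0.235	0.242	0.951	0.801	0.738	-0.596	7.2E-04
8	ICAM1	chr19:10242793-10243123	chr19:10081432-10081787	0.148	0.145	0.160	0.540	0.540	0.530	-0.383	2.8E-07
13	ProSAPiP1	chr20:3096748-3097085	chr10:36475835-36476155	0.400	0.355	0.446	0.183	0.170	0.130	0.239	1.5E-03
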