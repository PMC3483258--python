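# Replication of the validated DMRs in an independent cohort (2 humans H4-H5
# vs 4 rhesus macaques M4-M7), transcribed from the published study's
# replication table. The printed corrected p equals raw p x 3 (Bonferroni over
# the three replicated regions). NA = no eligible data.
dmr_id	gene	H4	H5	M4	M5	M6	M7	printed_difference	printed_p	printed_p_corrected
103	K6IRS2	0.289	0.252	0.936	0.852	0.902	0.958	-0.641	6.22E-05	1.9E-04
143	RNF32	0.403	0.427	0.930	0.875	0.925	NA	-0.495	2.6E-04	7.8E-04
8	ICAM1	0.103	0.200	0.455	0.520	0.410	0.500	-0.320	2.5E-03	7.5E-03
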