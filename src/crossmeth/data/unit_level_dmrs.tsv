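# Significantly differentially methylated CpG-unit pairs between human and
# rhesus macaque brain (3 vs 3 samples), transcribed from the published study's
# unit-level table. units_human / units_rhesus list the member CpG-unit labels
# of each merged orthologous unit group ("NA" marks a position with no
# orthologous counterpart unit on that side). Value NA = unreliable/missing
# measurement. printed_* columns as printed; the corrected p was adjusted over
# all 688 paired units, whose raw p-values are not published.
dmr_id	units_human	units_rhesus	H1	H2	H3	M1	M2	M3	printed_difference	printed_p	printed_p_corrected
8	16 NA	13 14	0.26	0.24	0.25	0.73	0.72	0.73	-0.48	2.3E-07	7.9E-05
8	15	12	0.17	0.12	0.19	0.55	0.58	0.49	-0.38	3.5E-04	8.6E-03
13	NA 4 5	13 12 NA	0.41	NA	0.41	0.17	0.12	0.14	0.27	7.5E-04	1.3E-02
13	14 15 16	NA 1 NA	0.49	NA	0.57	0.29	0.3	0.28	0.24	4.4E-03	4.0E-02
13	1 2	15 14	0.37	0.44	0.48	0.17	0.17	0.02	0.32	6.1E-03	5.0E-02
22	7 8 9 10	7 8 9 10	0.23	0.23	0.12	0.43	0.48	0.41	-0.25	4.3E-03	4.0E-02
51	17 18 19	16 17 18	0.07	0.02	0.05	NA	0.27	0.3	-0.24	1.6E-03	2.2E-02
57	9 NA 10 11	8 9 10 NA	0.11	0.13	0.08	0.67	NA	0.66	-0.56	8.8E-05	5.0E-03
57	29 NA	25 26	0	0	0	0.18	NA	0.25	-0.22	3.7E-03	3.8E-02
75	NA 1	1 2	0.76	0.75	0.8	1.00	1.00	1.00	-0.23	1.1E-04	5.1E-03
76	26 27	NA 1	1.00	1.00	1.00	0.62	0.59	0.69	0.37	2.4E-04	7.3E-03
103	9	9	0.01	0.03	0.03	0.77	0.69	0.6	-0.66	1.8E-04	6.5E-03
103	19	19	0.38	0.33	0.38	0.97	0.91	0.81	-0.53	4.2E-04	9.7E-03
103	4	3	0.14	0.07	0.13	1.00	0.81	0.75	-0.74	7.0E-04	1.3E-02
103	10 11 12 NA	10 11 NA 12	0.21	0.22	0.21	0.99	0.74	0.76	-0.62	1.5E-03	2.1E-02
103	5 NA 6 NA	4 5 NA 6	0.05	0.04	0.06	0.96	NA	0.74	-0.81	2.3E-03	2.6E-02
103	24	25	0.24	0.26	0.31	0.73	0.98	0.71	-0.54	3.9E-03	3.9E-02
122	3 4 5	NA 5 NA	0.87	0.77	0.87	0.26	0.26	0.24	0.58	6.8E-05	5.0E-03
127	18 19 NA	18 19 20	0.11	0.04	0.10	0.28	0.3	0.30	-0.21	7.8E-04	1.3E-02
131	43 44	31 32	0.21	0.24	0.27	0	0.03	0.01	0.23	3.1E-04	7.9E-03
139	15 16 NA 17 18 19	8 9 10 NA 11 NA	0.13	0.21	0.17	0.36	0.39	0.41	-0.22	1.4E-03	2.0E-02
141	45 46 47	43 NA 44	0.25	0.20	0.20	0.02	0.01	0.01	0.21	2.9E-04	7.9E-03
143	NA 3 NA	4 NA 5	0.30	0.29	0.35	1.00	1.00	0.99	-0.68	3.5E-06	7.9E-04
143	7	9	0.27	0.22	0.25	0.96	0.86	0.84	-0.64	8.8E-05	5.0E-03
143	5	7	0.29	0.27	0.33	0.85	0.75	0.80	-0.50	1.2E-04	5.1E-03
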