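scaffold	n_snps_q1	n_snps_q2	length_nt
scaffold_1	1267	716	46877626
scaffold_2	1205	412	26807724
scaffold_3	499	241	22025550
scaffold_4	412	227	30528727
scaffold_5	698	357	18502877
scaffold_6	392	217	28902582
scaffold_7	862	414	22790193
scaffold_8	1266	459	21829753
scaffold_9	9	4	2126789
scaffold_10	0	0	851981
scaffold_11	1	8	736058
scaffold_12	27	8	675284
scaffold_13	0	0	670721
scaffold_14	1	0	575512
scaffold_15	14	8	516056
scaffold_16	1	1	390024
scaffold_17	0	0	370749
scaffold_18	0	0	333953
scaffold_22	0	0	167479
scaffold_23	0	0	69963
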