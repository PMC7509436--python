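segment_id	chrom	amplicon_length_bp	copy_number	n_snps	n_haplotypes	hd_all	hd_distinct	pic
SEG1	Chr1	598	1	17	13	0.70	0.75	0.72
SEG2	Chr2	558	1	13	14	0.38	0.39	0.38
SEG3	Chr2	687	1	13	8	0.33	0.30	0.29
SEG4	Chr2	559	1	13	7	0.54	0.56	0.48
SEG5	Chr2	530	1	4	4	0.11	0.16	0.16
SEG6	Chr3	571	1	12	15	0.82	0.84	0.82
SEG7	Chr4	580	2	15	10	0.79	0.78	0.75
SEG8	Chr4	431	1	10	8	0.50	0.53	0.50
SEG9	Chr6	720	1	14	9	0.41	0.41	0.37
SEG10	Chr6	654	1	6	7	0.24	0.29	0.29
SEG11	Chr6	722	2	7	7	0.23	0.25	0.25
SEG12	Chr6	594	1	13	11	0.84	0.84	0.82
SEG13	Chr7	645	1	4	3	0.16	0.19	0.17
SEG14	Chr7	454	2	1	2	0.09	0.11	0.12
SEG15	Chr7	541	2	9	7	0.28	0.27	0.27
SEG16	Chr7	561	1	5	4	0.06	0.07	0.07
SEG17	NA	665	1	10	7	0.49	0.50	0.45
SEG18	Chr6	563	1	3	4	0.10	0.15	0.14
SEG19	Chr2	576	1	7	8	0.59	0.61	0.54
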