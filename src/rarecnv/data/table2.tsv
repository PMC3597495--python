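#patient	inheritance	cnv_type	locus	chrom	start_mb	end_mb	size_kb	n_genes	sos_genes	md_syndrome	n_growth_function	n_gepis_tissue	n_decipher	n_diff_expressed	n_expr_genes	n_mgi_growth	gwas_min_p	gwas_significant	breakpoint_genes	n_hi_genes
1	de_novo	loss	1q32.1	chr1	204.2	206.6	2157	33	-	-	5	6	0	10	33	3	4.5e-4	0	PLEKHA6,SRGAP2	3
2	de_novo	loss	2q36.1-36.3	chr2	221.9	228.6	6695	31	PAX3	-	3	8	2	7	28	4	2.17e-8	1	-	5
3	de_novo	loss	14q23.1	chr14	57.1	58.4	1352	8	-	-	1	3	0	2	8	1	1.19e-2	0	C14orf37	3
4	de_novo	loss	22q11.21-11.22	chr22	21.6	22.9	1363	23	-	22q11.2	5	5	4	.	.	2	1.1e-3	0	-	3
5	de_novo	gain	2p23.3	chr2	25.2	29.7	4573	77	POMC,GCKR	-	13	21	0	24	77	7	2.79e-13	1	-	8
6	de_novo	gain	19q13.43	chr19	58.3	58.7	367	13	-	-	10	3	0	1	13	1	1.26e-1	0	-	0
7	de_novo	gain	3q29	chr3	195.7	197.3	1653	29	-	3q29	5	4	0	11	29	5	8.33e-3	0	-	3
8	maternal	loss	1q21.1	chr1	146.1	148.6	2116	26	-	1q21	3	2	3	.	.	0	1.42e-6	0	-	2
9	maternal	loss	22q11.22	chr22	22.3	22.5	259	1	-	22q11.2	1	0	2	0	1	0	4.29e-2	0	TOP3B	0
10	maternal	gain	17q11.2	chr17	30.8	31.2	393	2	-	-	0	2	0	.	.	0	5.57e-2	0	-	0
11	maternal	gain	5q22.1-q23.2	chr5	110.0	124.2	14229	59	-	-	12	17	0	.	.	7	2.08e-8	1	-	2
12	maternal	gain	1q21.1	chr1	145.6	145.9	307	6	-	1q21.1/TAR	0	1	1	3	6	0	2.39e-3	0	-	0
13	maternal	gain	2q33.2	chr2	203.4	203.7	323	3	-	2q33	1	1	0	.	.	1	1.01e-4	0	-	1
14	maternal	gain	7q36.3	chr7	156.9	157.1	165	1	-	-	0	1	1	.	.	0	1.13e-2	0	-	0
15	maternal	gain	1p36.33	chr1	0.9	1.2	306	20	-	1p36	1	3	0	.	.	1	5.25e-2	0	-	1
16	maternal	gain	2q21.2	chr2	133.1	133.7	598	3	-	-	0	0	1	.	.	0	8.76e-4	0	-	0
17	paternal	loss	13q22.1	chr13	73.4	73.5	118	1	-	-	0	0	2	0	1	0	1.43e-2	0	PIBF1	0
18	paternal	loss	14q21.1-q21.2	chr14	40.2	42.1	1871	1	-	-	0	0	1	0	1	0	4.32e-2	0	LRFN5	0
19	paternal	loss	1q21.1	chr1	145.9	147.8	1654	17	-	1q21	3	2	3	2	15	0	1.42e-6	0	-	2
20	paternal	loss	5p15.33	chr5	0.6	0.7	109	1	-	-	1	0	0	.	.	0	1.11e-1	0	TPPP	0
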