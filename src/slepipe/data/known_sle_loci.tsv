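snp_id	chrom	pos	cytoband	gene_label	allele1	allele2	freq_case	freq_control	or_reported	p_reported	eqtl_positive	discovered_in
rs2205960	1	171458098	1q25	TNFSF4	T	G	0.23	0.18	1.35	3.0e-6	0	caucasian
rs3024505	1	205006527	1q32	IL10	A	G	0.019	0.014	1.34	0.15	0	caucasian
rs13385731	2	33555394	2p22	RASGRP3	C	T	0.90	0.87	1.37	6.0e-4	1	asian
rs10168266	2	191644049	2q32	STAT4	T	C	0.37	0.27	1.59	2.7e-16	0	caucasian
rs6445975	3	58345217	3p14	PXK	G	T	0.25	0.23	1.09	0.18	1	caucasian
rs10516487	4	102970099	4q24	BANK1	G	A	0.91	0.89	1.28	0.0070	0	caucasian
rs10036748	5	150438339	5q33	TNIP1	T	C	0.75	0.72	1.16	0.014	0	asian
rs9501626	6	32508322	6p21	HLA-DRB1	A	C	0.20	0.12	1.86	1.0e-18	0	caucasian
rs548234	6	106674727	6q21	PRDM1	C	T	0.40	0.34	1.30	2.3e-6	1	caucasian
rs2230926	6	138237759	6q23	TNFAIP3	G	T	0.11	0.069	1.75	1.9e-10	1	caucasian
rs849142	7	28152416	7p15	JAZF1	C	T	0.999	0.999	2.72	0.41	0	caucasian
rs4917014	7	50276409	7p12	IKZF1	T	G	0.58	0.53	1.24	8.1e-5	0	asian
rs6964720	7	75018280	7q11	HIP1	G	A	0.25	0.19	1.43	1.3e-8	0	asian
rs4728142	7	128361203	7q32	IRF5	A	G	0.16	0.11	1.48	2.4e-7	1	caucasian
rs2254546	8	11381089	8p23	BLK	G	A	0.78	0.72	1.42	4.1e-8	1	caucasian
rs1913517	10	49789060	10q11	WDFY4	A	G	0.32	0.28	1.20	0.0013	0	asian
rs4963128	11	579564	11p15	KIAA1542	T	C	0.98	0.97	1.58	0.038	1	caucasian
rs2732552	11	35041168	11p13	PDHX,CD44	T	C	0.75	0.73	1.13	0.056	0	caucasian
rs4639966	11	118078729	11q23	intergenic	T	C	0.32	0.28	1.22	7.3e-4	0	asian
rs6590330	11	127816269	11q24	ETS1	A	G	0.48	0.39	1.44	1.3e-11	0	asian
rs1385374	12	127866647	12q24	SLC15A4	T	C	0.19	0.16	1.21	0.0057	0	asian
rs7329174	13	40456110	13q14	ELF1	G	A	0.30	0.25	1.32	2.2e-6	0	asian
rs7197475	16	30550368	16p11	intergenic	T	C	0.12	0.10	1.20	0.031	0	asian
rs11150610	16	31241737	16p11	ITGAM	C	A	0.20	0.19	1.07	0.32	1	caucasian
rs12949531	17	13674531	17p12	intergenic	T	C	0.28	0.27	1.02	0.73	0	caucasian
rs463426	22	20139185	22q11	HIC2,UBE2L3	T	C	0.52	0.48	1.20	6.1e-4	0	caucasian
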