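tag_id	length	sequence	origin	genomic_distribution	associated_gene	rpkm_pgc	rpkm_stagex	rpkm_gsc	rpkm_cef	fold_change_reported
ISG_3439104	25	TATTTCCTAACGTCCAGCCTGAACC	repeat	LINE/CR1:0	.	1147.02	13.07	13.52	0	129.42
ISG_1952422	27	CCAGAACACACTTGGCCTTCCGGGCTG	repeat	LINE/CR1:0	.	928.3	3.78	17.55	0	130.55
ISG_2828838	25	CACTGATGGACAGGTCCTGGCTAAG	repeat	LTR/ERVL:1	.	251.4	2.68	3.92	0	114.24
ISG_1920655	27	ACTGAACACAGCACTCGAGGTGAGGCC	repeat	LINE/CR1:0	.	242.5	2.83	3.49	0	115.05
ISG_587310	25	TATTTCCTAACGTCCAGCCTGAATC	repeat	Ambi	.	215.07	1.73	2.29	0	160.43
ISG_434349	27	TCCTTGCACAGCCACGACAGTCGCCTG	repeat	LINE/CR1:0	.	205.56	0.31	3.6	0	157.61
ISG_3712010	25	TACCTGTAGAACCCCTTCTTGTTGT	repeat	LINE/CR1:0	.	194.22	0.63	4.03	0	124.93
ISG_347271	28	TTGAACCTCATTAGGTTTTCGTGGGACC	repeat	LINE/CR1:0	.	175.2	2.36	2.83	0	101.14
ISG_471296	27	TGCACTCGATGCCATCGTCTGTCACTG	repeat	LINE/CR1:0	.	169.35	0.47	4.03	0	112.74
ISG_2635821	26	TTCCAGCGTTGTGTGATTTTAGAAGC	repeat	LINE/CR1:1	.	155.45	0.63	3.16	0	123
ISG_2618644	26	TGCTGACGGACTTCCCTGGGCCTGCT	repeat	LTR/ERVL:1	.	150.81	0.16	1.85	0	225
ISG_3554587	29	TCTGATCATCCTCTGGACTTGCTCCAAGA	repeat	LINE/CR1:0	.	149.72	0.63	2.51	0	143.16
ISG_3050277	25	TTTTGACTTAAAAAACGTGTGCGCC	repeat	LTR/ERVL:1	.	144.48	2.99	1.09	0	106.18
ISG_1247918	25	AAGAAAGACGCAGAGCTCTTGGACC	repeat	LINE/CR1:1	.	130.09	0.79	3.05	0	101.63
ISG_2559548	26	TTTCCATCCCTCACTGTCTCTGAGCT	repeat	LINE/CR1:0	.	120.94	0.16	2.07	0	162.79
ISG_2994213	27	TGTACCTGTAGAACCCCTTCTTGTTGT	repeat	LINE/CR1:0	.	119.36	0	1.74	0	205.28
ISG_2004249	23	TTTCCTAACGTCCAGCCTGAACC	repeat	LINE/CR1:0	.	110.95	0.16	1.64	0	185.66
ISG_988698	26	GATGATCAGAGGGCTGGAGCACCTCC	repeat	LINE/CR1:1	.	110.22	0.63	1.96	0	127.55
ISG_1691836	26	TGTACCTGTAGAACCCCTTCTTGTTG	repeat	LINE/CR1:0	.	109.73	0.16	1.64	0	183.61
ISG_2499527	25	AGGAATGGGCTGCCCAGAGAGGTGG	repeat	LINE/CR1:1	.	108.39	0	1.53	0	213.04
ISG_2943457	25	GACAGACAGAGCTGCCCCTGAGCCT	genic	Intron_antisense	CHIR-B5	55.72	0	0.87	0	191.65
ISG_1259042	27	AGACTGAAGATGTGCACCTGACGCCAG	genic	Intron_sense	CHIR-AB1	49.62	0	0.76	0	195.06
ISG_2785619	26	TTCTGCATGTTGCTCTCTGTCAGCTG	genic	Intron_sense	PLLP	42.92	0	0.33	0	393.64
ISG_2237691	25	AGACTGAAGATCTGCACCTGACACC	genic	Intron_sense	CHIR-B5	35.6	0	0.87	0	122.45
ISG_2022559	27	TGTTTACTGACTGAGCTACTTTTCCCC	genic	Intron_sense	MYO1A	33.41	0	0.11	0	919.25
ISG_2633063	26	AGGGTACTGAGACATCTTGGAGACAA	genic	Intron_antisense	SLC6A2	19.87	0	0.33	0	182.28
ISG_1354003	21	TTTCCAAGGACCAGTAGCGCT	genic	Intron_sense	17.5	18.29	0	0.55	0	100.65
ISG_2087909	26	TCTCAAAGGATTCCGCATCGTCGACG	genic	Exon_antisense	RAP2B	11.95	0	0	0	1194.81
ISG_3065006	28	AAGGACCCAAATGGTAGCAGAGGCCATG	genic	Intron_antisense	LRP8	9.51	0	0.11	0	261.68
ISG_3356981	25	AATGCTGAGAACTAAGGATGCCTCC	genic	Intron_sense	VDR	7.92	0	0	0	792.48
ISG_3294350	30	CAGGCTGTGACCCTGGAATTCCACTACACT	genic	Intron_sense	MYH1E	7.44	0	0.11	0	204.65
ISG_2645108	27	GAGTGTGAGAAGGGCTTTGTGCAGAGC	genic	Exon_antisense	ZNF302	5.24	0	0	0	524.26
ISG_2675670	23	CGGTGTGGGACGAGAAGGAGAAC	genic	Exon_sense	RGN	4.88	0	0	0	487.68
ISG_3080707	27	CTGTGAGTGTGTGAGTGCGGCGGCGCG	genic	Intron_antisense	FOXD2	4.27	0	0.11	0	117.42
ISG_3280151	24	AAGGACCTCTGAGAATTGCTTTCT	genic	Exon_sense	RASSF2	2.32	0	0	0	231.65
ISG_1621199	27	CAGAAGAGAAGCTGAACACAGGGTGTC	genic	Intron_antisense	VAMP7	1.95	0	0	0	195.07
ISG_882291	28	TTAAAGATATTTGGCTGCCTGGCTCGCC	genic	Intron_sense	NLGN1	1.95	0	0	0	195.07
ISG_2363541	26	AAGGACACCGAGGCTCTGCGTGCTGA	genic	Exon_sense	APOA1	1.83	0	0	0	182.88
ISG_2033456	26	TCGGCTCGGCTCGGCTCGGCTCGGCT	genic	Exon_antisense	ADK	1.1	0	0	0	109.73
ISG_950928	27	ATCTGCGTTTAAAGCTCTTTGCACACT	genic	Intron_antisense	PLLP	1.1	0	0	0	109.73
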