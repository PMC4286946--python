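category	PGCs	Stage X	GSCs	CEFs
Repeat	14624	7395	5	49
Unannotated	8394	9335	1248	2181
rRNAs	1281	7245	3141	1261
Intron sense	629	566	4	84
tRNAs	507	1831	37	554
Intron antisense	320	180	8	51
Exon sense	251	435	49	67
scRNA	92	124	20	44
miRNAs	96	448	324	742
snoRNA	75	165	96	79
snRNA	53	151	35	9
Exon antisense	6	28	0	7
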