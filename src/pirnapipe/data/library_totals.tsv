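sample	raw_reads	raw_bases	clean_reads	clean_bases	min_len	max_len	unique_reads
PGCs	9175177	449583673	8199557	193849279	18	44	1010670
Stage X	9243725	452942525	6341942	154246061	18	44	487258
GSCs	10314115	505391635	9169772	208574068	18	44	462903
CEFs	16705966	818592334	15180321	334940464	18	44	217402
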