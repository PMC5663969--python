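#sample	raw_reads	post_filter_reads	pct_rrna	short_pool	mirbase_mapped	ensembl_mapped
C1	18085235	1653832	75.9	458186	33157	576866
C3	7843315	727633	73.4	221985	23594	170592
C13	13830831	1148352	74.8	291302	14734	358268
C15	10111670	1023795	73.8	300569	25465	232061
C16	10936417	1509424	69.3	390705	40801	526181
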