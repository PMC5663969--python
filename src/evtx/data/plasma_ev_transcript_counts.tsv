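#sample	protein_coding	pseudogene	long_noncoding	short_noncoding	mirna_mature	trna	misc_rna	other
C1	7824	91	220	765	181	220	218	146
C3	5461	34	101	554	163	172	110	109
C13	7937	83	207	738	157	259	189	133
C15	6134	44	131	626	162	217	133	114
C16	8660	171	211	887	216	235	254	182
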