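#biotype	major_category	subcategory	misc_subtype
protein_coding	protein_coding	.	.
IG_C_gene	protein_coding	.	.
IG_V_gene	protein_coding	.	.
TR_C_gene	protein_coding	.	.
TR_V_gene	protein_coding	.	.
pseudogene	pseudogene	.	.
processed_pseudogene	pseudogene	.	.
unprocessed_pseudogene	pseudogene	.	.
transcribed_processed_pseudogene	pseudogene	.	.
transcribed_unprocessed_pseudogene	pseudogene	.	.
polymorphic_pseudogene	pseudogene	.	.
unitary_pseudogene	pseudogene	.	.
IG_C_pseudogene	pseudogene	.	.
IG_V_pseudogene	pseudogene	.	.
TR_V_pseudogene	pseudogene	.	.
lincRNA	long_noncoding	.	.
antisense	long_noncoding	.	.
processed_transcript	long_noncoding	.	.
sense_intronic	long_noncoding	.	.
sense_overlapping	long_noncoding	.	.
3prime_overlapping_ncrna	long_noncoding	.	.
non_coding	long_noncoding	.	.
miRNA	short_noncoding	miRNA	.
tRNA	short_noncoding	tRNA	.
Mt_tRNA	short_noncoding	Mt_tRNA	.
Mt_rRNA	short_noncoding	Mt_rRNA	.
rRNA	short_noncoding	rRNA	.
snoRNA	short_noncoding	snoRNA	.
snRNA	short_noncoding	snRNA	.
misc_RNA	short_noncoding	misc_RNA	.
Y_RNA	short_noncoding	misc_RNA	Y_RNA
SRP_7SL_RNA	short_noncoding	misc_RNA	SRP_7SL_RNA
SRP_RNA	short_noncoding	misc_RNA	SRP_7SL_RNA
7SL_RNA	short_noncoding	misc_RNA	SRP_7SL_RNA
Vault_RNA	short_noncoding	misc_RNA	Vault_RNA
vaultRNA	short_noncoding	misc_RNA	Vault_RNA
7SK_RNA	short_noncoding	misc_RNA	7SK_RNA
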