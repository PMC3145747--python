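pigmentation_gene_set	positive control: pigmentation loci from published GWAS	SLC45A2	IRF4	EXOC2	TYPR1	TPCN2	TYR	KITLG	SLC24A4	OCA2	MC1R	ASIP	HERC2
bcc_risk_gene_set	positive control: basal cell carcinoma risk loci from published GWAS	PADI6	RHOU	SLC45A2	TERT	CLPTM1L	KLF14	CDKN2A	CDKN2B	TYR	KRT5	MC1R	ASIP	PTCH1
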