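##gff-version 3
BDNF_like_fixture	.	exon	1	27	.	+	.	ID=exon1
BDNF_like_fixture	.	exon	28	44	.	+	.	ID=exon2
BDNF_like_fixture	.	CDS	33	44	.	+	.	ID=cds1
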