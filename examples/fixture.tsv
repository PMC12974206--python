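transcript_id	exon_lengths	cds_start	cds_end
BDNF_like_fixture	27,17	32	44
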