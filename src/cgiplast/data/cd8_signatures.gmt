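CD8_SIGNATURE_A	cytotoxic CD8 T-cell infiltration signature	CCL2	CCL3	CCL4	CXCL9	CXCL10	CD8A	HLA-DOB	HLA-DMB	HLA-DOA	GZMK	ICOS	IRF1
CD8_SIGNATURE_B	cytolytic activity signature	GZMA	PRF1
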