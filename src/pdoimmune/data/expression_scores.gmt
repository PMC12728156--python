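antigen_presentation	MHC class I antigen presentation	HLA-A	HLA-B	HLA-C	B2M	TAP1
melanocytic	melanocytic differentiation program	SOX10	MITF	TYR	PMEL
dedifferentiated	dedifferentiated melanoma program	SOX10	NGFR	AXL
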