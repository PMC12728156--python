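T_cell	T lymphocyte markers	CD3D	CD3E	CD3G	CD2	CD5	TRAC
CD8_T_cell	CD8 T cell markers	CD8A	CD8B
cytotoxicity	cytotoxic effector markers	GZMA	GZMB	PRF1	NKG7	KLRD1
B_lineage	B lymphocyte markers	CD19	MS4A1	CD79A	CD79B	IGHM
NK_cell	natural killer markers	NCR1	KLRC1	KIR2DL3
monocytic	monocyte/macrophage markers	CD14	CD163	CSF1R	FCGR3A	ITGAM
myeloid_dendritic	myeloid dendritic cell markers	CD1C	FLT3	CLEC10A
neutrophil	neutrophil markers	FCGR3B	CSF3R	S100A8	S100A9
endothelial	endothelial markers	PECAM1	VWF	CDH5	KDR
fibroblast	fibroblast markers	COL1A1	COL1A2	COL3A1	DCN	PDGFRB	FAP
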