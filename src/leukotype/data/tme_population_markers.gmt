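t_cells	default markers	CD3D	CD3E	CD3G	CD28
cd8_t_cells	default markers	CD8A	CD8B
cytotoxic_lymphocytes	default markers	GZMA	GZMB	PRF1	KLRK1
nk_cells	default markers	NCR1	KIR2DL3	KLRD1
b_cell_lineage	default markers	CD19	MS4A1	CD79A	CD79B
monocytic_lineage	default markers	CD14	CSF1R	ITGAM
myeloid_dendritic_cells	default markers	CD1C	CLEC10A	FCER1A
neutrophils	default markers	FCGR3B	CSF3R	CEACAM3
endothelial_cells	default markers	PECAM1	VWF	CDH5	KDR
fibroblasts	default markers	COL1A1	COL3A1	DCN	PDGFRB
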