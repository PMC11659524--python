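MHCI	group=antitumor_immune	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2	NLRC5
MHCII	group=antitumor_immune	HLA-DRA	HLA-DRB1	HLA-DMA	HLA-DPA1	HLA-DPB1	CIITA	HLA-DQB1
Coactivation_molecules	group=antitumor_immune	CD28	CD40	CD80	CD86	CD83	TNFRSF4	ICOSLG	CD27
Effector_cells	group=antitumor_immune	IFNG	GZMA	GZMB	PRF1	KLRK1	ZAP70	GNLY	FASLG
T_cells	group=antitumor_immune	CD3D	CD3E	CD3G	TRAC	CD28	CD5	TRBC2
T_cell_traffic	group=antitumor_immune	CXCL9	CXCL10	CXCL11	CCL5	CXCR3	CCL4
NK_cells	group=antitumor_immune	KLRD1	NKG7	KIR2DL4	NCR1	KLRC2	EOMES	FGFBP2
B_cells	group=antitumor_immune	CD19	MS4A1	CD79A	CD79B	BLK	CR2	TNFRSF13C
M1_signature	group=antitumor_immune	NOS2	IL1B	IL12A	IL12B	SOCS3	IL23A	TNF
Th1_signature	group=antitumor_immune	IFNG	IL2	CD40LG	IL15	TBX21	IL21	STAT4
Antitumor_cytokines	group=antitumor_immune	TNF	IFNB1	IL21	CCL3	TNFSF10	IFNA2
Checkpoint_inhibition	group=protumor_immune	PDCD1	CD274	CTLA4	LAG3	HAVCR2	PDCD1LG2	BTLA	VSIR
Treg	group=protumor_immune	FOXP3	IL10	TNFRSF18	CTLA4	IKZF2	IKZF4
Treg_traffic	group=protumor_immune	CCL17	CCL22	CCL1	CCL28	CCR4	CCR8	CCR10
Neutrophil_signature	group=protumor_immune	FCGR3B	CD177	CTSG	ELANE	PRTN3	MPO
Granulocyte_traffic	group=protumor_immune	CXCL8	CXCL2	CXCL1	CXCR1	CXCR2	CCL11	KITLG
MDSC	group=protumor_immune	ARG1	IL10	IDO1	IL4I1	PTGS2	IL6	CYBB
MDSC_traffic	group=protumor_immune	CSF1	CSF2	CSF3	CCL15	CXCL5	CXCL12	IL6R
Macrophages	group=protumor_immune	CD68	CD163	MRC1	MSR1	CSF1R	SIGLEC1
Macrophage_DC_traffic	group=protumor_immune	CCL2	CCL7	CCL8	CSF1	XCL1	CCR2	XCR1
Th2_signature	group=protumor_immune	IL4	IL5	IL13	GATA3	IL10	CCR4
Protumor_cytokines	group=protumor_immune	IL6	IL10	TGFB1	TGFB2	TGFB3	IL22	MIF
CAF	group=angiogenesis_stroma	FAP	COL1A1	COL1A2	COL5A1	ACTA2	PDGFRB	FBLN1	LUM
Matrix	group=angiogenesis_stroma	FN1	COL11A1	COL3A1	COL4A1	LAMB3	TNC	VTN	LGALS9
Matrix_remodeling	group=angiogenesis_stroma	MMP1	MMP2	MMP3	MMP9	MMP12	PLOD2	ADAMTS4	LOX
Angiogenesis	group=angiogenesis_stroma	VEGFA	VEGFB	VEGFC	PDGFC	ANGPT1	ANGPT2	KDR	TEK
Endothelium	group=angiogenesis_stroma	PECAM1	CDH5	VWF	CLDN5	FLT1	ENG	NOS3	MMRN1
Proliferation_rate	group=malignant_properties	MKI67	CCNE1	CCND1	AURKA	AURKB	BUB1	E2F1	MYBL2
EMT_signature	group=malignant_properties	SNAI1	SNAI2	TWIST1	ZEB1	ZEB2	CDH2	VIM	FN1
Hypoxia	group=malignant_properties	HIF1A	CA9	SLC2A1	VEGFA	LDHA	PGK1	ADM
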