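EMT_UP	synthetic stand-in: 52 mesenchymal markers (canonical symbols, published set size)	VIM	FN1	CDH2	ZEB1	ZEB2	SNAI1	SNAI2	TWIST1	TWIST2	FOXC2	PRRX1	MMP2	MMP3	MMP9	MMP14	SPARC	THBS1	THBS2	COL1A1	COL1A2	COL3A1	COL5A1	COL5A2	COL6A1	COL6A2	COL6A3	FBN1	POSTN	TNC	LOX	LOXL2	PDGFRA	PDGFRB	AXL	EMP3	ITGA5	ITGB1	TGFB1	TGFB1I1	TGFBI	SERPINE1	SERPINE2	TIMP1	WNT5A	WNT5B	GREM1	DCN	LUM	FAP	ACTA2	TAGLN	CALD1
EMT_DOWN	synthetic stand-in: 25 epithelial markers (canonical symbols, published set size)	CDH1	ESRP1	ESRP2	GRHL2	GRHL3	CLDN1	CLDN3	CLDN4	CLDN7	OCLN	TJP3	DSP	DSG3	DSC2	KRT5	KRT8	KRT14	KRT18	KRT19	EPCAM	CTNND1	F11R	MARVELD3	RAB25	ST14
ECM_UP	synthetic stand-in: 30 cancer-ECM up genes (canonical symbols, published set size)	COL1A1	COL1A2	COL3A1	COL5A1	COL5A2	COL10A1	COL11A1	FN1	POSTN	THBS2	SPP1	CTHRC1	SULF1	FAP	LOXL2	MMP1	MMP7	MMP9	MMP11	MMP12	ADAM12	INHBA	COMP	TNC	VCAN	FBN1	LTBP2	BGN	TGFBI	SERPINH1
ECM_DOWN	synthetic stand-in: 28 cancer-ECM down genes (canonical symbols, published set size)	ABI3BP	OGN	OMD	PRELP	FMOD	CHAD	TNXB	MFAP4	LAMA2	COL4A3	COL4A4	COL6A6	NPNT	SPOCK2	GPM6B	DPT	FBLN5	ELN	MGP	CILP	CILP2	ACAN	HMCN1	SMOC2	EMILIN2	LTBP4	PCOLCE2	SRPX
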