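titr	tumor-infiltrating Tregs	CCR8	TNFRSF4	TNFRSF9	IL2RA	FOXP3
mdsc	myeloid-derived suppressor cells	ARG1	S100A8	S100A9	ITGAM	CD33
c_ecm	cancer-associated extracellular matrix	COL1A1	COL1A2	COL5A1	FN1	LOX
wnt_tgfb	Wnt/TGF-beta program	WNT5A	TGFB1	TGFB2	SMAD3	CTNNB1
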