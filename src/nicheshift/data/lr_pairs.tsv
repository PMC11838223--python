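ligand	receptor
TNFSF12	TNFRSF12A
TNF	TNFRSF1A
TGFB1	TGFBR1
IL7	IL7R
CCL5	CCR5
CXCL12	CXCR4
FLT3LG	FLT3
KITLG	KIT
CSF1	CSF1R
CCL2	CCR2
CD40LG	CD40
FASLG	FAS
IL6	IL6R
IL10	IL10RA
JAG1	NOTCH1
TNFSF10	TNFRSF10A
IL2	IL2RA
ICAM1	ITGAL
VCAM1	ITGA4
VEGFA	FLT1
ANGPT1	TEK
HGF	MET
DLL1	NOTCH2
IL15	IL15RA
CXCL8	CXCR1
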