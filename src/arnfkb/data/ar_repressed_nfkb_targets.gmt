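AR_REPRESSED_NFKB_TARGETS	NF-kB target genes with reduced expression in high-AR-signature prostate tumors	CSF1	IL6	PTAFR	BCL3	CCR7	CCL5	RELB	CXCL5	MMP9	PLAU	HMOX1	CCL11	CR2	CD80	TNFRSF9	IL15RA	IFNB1	CCL15	BDKRB1	IL2RA	LTB	APOC3	IL13	IL1RN	PTX3	CRP	IL1A	CSF2	IL9
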