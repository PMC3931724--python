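CIG16	core invasiveness gene signature	BIRC3	C1S	CDH1	CTGF	FN1	c-FOS	IGFBP5	JUN	LTBP1	LYN	S100A8	SOX4	SPP1	STC1	THBS1	TNFAIP3
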