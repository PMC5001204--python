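term	category	genes	p_value
Response to drug	GO_BP	ABCB1,UGT1A4,CAV1,CAV2	3.6E-2
Metabolism of xenobiotics by cytochrome P450	KEGG	UGT1A4,ADH6,CYP1A1,CYP2C19,CYP2C9,CYP2E1	2.0E-4
Retinol metabolism	KEGG	UGT1A4,ADH6,CYP1A1,CYP2C19,CYP2C9	1.4E-3
Drug metabolism	KEGG	UGT1A4,ADH6,CYP2C19,CYP2C9,CYP2E1	2.4E-3
Linoleic acid metabolism	KEGG	CYP2C19,CYP2C9,CYP2E1	2.7E-2
Pathways in cancer	KEGG	CEBPA,CREBBP,SMAD3,TRAF2,BIRC3,EGLN2,FN1,IKBKG	2.9E-2
Focal adhesion	KEGG	BIRC3,CAV1,CAV2,FN1,ITGA1,THBS1	3.7E-2
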