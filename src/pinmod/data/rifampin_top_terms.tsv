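category	term	count	percent	p_value	benjamini
GO_BP	regulation of apoptosis	19	22.6	5.10E-07	7.30E-04
GO_BP	regulation of programme cell death	19	22.6	5.90E-07	4.20E-04
GO_BP	regulation of cell death	19	22.6	6.20E-07	3.00E-04
GO_BP	negative regulation of apoptosis	13	15.5	7.90E-07	2.80E-04
GO_BP	negative regulation of programmed cell death	13	15.5	9.10E-07	2.60E-04
GO_BP	negative regulation of cell death	13	15.5	9.40E-07	2.20E-04
GO_BP	membrane organization	13	15.5	1.70E-06	3.50E-04
GO_BP	vesicle-mediated transport	15	17.9	4.50E-06	8.10E-04
GO_BP	membrane invagination	10	11.9	4.70E-06	7.40E-04
GO_BP	endocytosis	10	11.9	4.70E-06	7.40E-04
GO_BP	response to hypoxia	8	9.5	1.20E-05	1.70E-03
GO_BP	response to oxygen levels	8	9.5	1.60E-05	2.10E-03
GO_BP	response to inorganic substance	9	10.7	2.30E-05	2.70E-03
GO_BP	anti-apoptosis	9	10.7	2.40E-05	2.60E-03
GO_BP	positive regulation of multicellular organismal process	9	10.7	7.90E-05	8.00E-03
GO_BP	drug metabolic process	4	4.8	9.80E-05	9.20E-03
GO_BP	response to metal ion	7	8.3	9.80E-05	8.70E-03
GO_BP	phagocytosis	5	6.0	1.60E-04	1.40E-02
GO_BP	response to organic substance	14	16.7	2.20E-04	1.80E-02
GO_BP	regulation of tube size	5	6.0	2.40E-04	1.80E-02
KEGG	Metabolism of xenobiotics by cytochrome P450	6	7.1	2.00E-04	1.70E-02
KEGG	Retinol metabolism	5	6.0	1.40E-03	6.00E-02
KEGG	Drug metabolism	5	6.0	2.40E-03	6.70E-02
KEGG	Linoleic acid metabolism	3	3.6	2.70E-02	4.50E-01
KEGG	Pathways in cancer	8	9.5	2.90E-02	4.00E-01
KEGG	Focal adhesion	6	7.1	3.70E-02	4.10E-01
KEGG	Porphyrin and chlorophyll metabolism	3	3.6	3.70E-02	3.70E-01
KEGG	Small cell lung cancer	4	4.8	4.20E-02	3.70E-01
KEGG	ECM-receptor interaction	4	4.8	4.20E-02	3.70E-01
KEGG	TGF-beta signaling pathway	4	4.8	4.60E-02	3.60E-01
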