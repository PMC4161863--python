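pathway	enrichment_p	gene_id	gene_symbol	cox_coefficient	cox_p	stability
Cytokine Cytokine Receptor Interaction	0.029	355	FAS	-0.42	0.0048	0.9925
Cytokine Cytokine Receptor Interaction	0.029	1235	CCR6	-0.22	0.023	0.905
Cytokine Cytokine Receptor Interaction	0.029	1439	CSF2RB	-0.32	0.0046	0.9875
Cytokine Cytokine Receptor Interaction	0.029	2322	FLT3	-0.28	0.015	0.93
Cytokine Cytokine Receptor Interaction	0.029	3561	IL2RG	-0.20	0.031	0.8125
Cytokine Cytokine Receptor Interaction	0.029	3570	IL6R	-0.37	0.027	0.85
Cytokine Cytokine Receptor Interaction	0.029	3575	IL7R	-0.23	0.0044	0.995
Cytokine Cytokine Receptor Interaction	0.029	4982	TNFRSF11B	-0.22	0.019	0.9125
Cytokine Cytokine Receptor Interaction	0.029	6363	CCL19	-0.11	0.033	0.8025
Cytokine Cytokine Receptor Interaction	0.029	6375	XCL1	-0.21	0.013	0.9575
Cytokine Cytokine Receptor Interaction	0.029	7042	TGFB2	-0.24	0.016	0.9325
Cytokine Cytokine Receptor Interaction	0.029	7422	VEGFA	0.15	0.031	0.83
Chemokine Signaling Pathway	0.041	112	ADCY6	0.34	0.032	0.8225
Chemokine Signaling Pathway	0.041	1235	CCR6	-0.22	0.023	0.905
Chemokine Signaling Pathway	0.041	3702	ITK	-0.18	0.023	0.87
Chemokine Signaling Pathway	0.041	3717	JAK2	-0.48	0.0025	1
Chemokine Signaling Pathway	0.041	5579	PRKCB1	-0.39	0.021	0.8975
Chemokine Signaling Pathway	0.041	5613	PRKX	-0.26	0.031	0.8155
Chemokine Signaling Pathway	0.041	5829	PXN	0.34	0.021	0.8725
Chemokine Signaling Pathway	0.041	6363	CCL19	-0.11	0.033	0.8025
Chemokine Signaling Pathway	0.041	6375	XCL1	-0.21	0.013	0.9575
Cell Cycle	0.012	894	CCND2	-0.27	0.013	0.96
Cell Cycle	0.012	1021	CDK6	-0.48	0.010	0.955
Cell Cycle	0.012	1869	E2F1	0.32	0.0015	1
Cell Cycle	0.012	1870	E2F2	0.33	0.031	0.8375
Cell Cycle	0.012	7042	TGFB2	-0.24	0.016	0.9325
Cell Cycle	0.012	8243	SMC1A	0.75	0.0085	0.98
Cell Cycle	0.012	9700	ESPL1	0.25	0.010	0.97
Cell Cycle	0.012	10744	PTTG2	0.46	0.011	0.975
Natural Killer Cell Mediated Cytotoxicity	0.048	355	FAS	-0.42	0.0048	0.9925
Natural Killer Cell Mediated Cytotoxicity	0.048	3002	GZMB	-0.23	0.0067	0.985
Natural Killer Cell Mediated Cytotoxicity	0.048	3383	ICAM1	-0.32	0.022	0.8975
Natural Killer Cell Mediated Cytotoxicity	0.048	3821	KLRC1	-0.43	0.0073	0.97
Natural Killer Cell Mediated Cytotoxicity	0.048	3932	LCK	-0.24	0.025	0.875
Natural Killer Cell Mediated Cytotoxicity	0.048	5579	PRKCB1	-0.39	0.021	0.8975
Natural Killer Cell Mediated Cytotoxicity	0.048	22914	KLRK1	-0.34	0.015	0.9325
T Cell Receptor Signaling Pathway	0.046	917	CD3G	-0.43	0.00097	0.9975
T Cell Receptor Signaling Pathway	0.046	3702	ITK	-0.18	0.023	0.87
T Cell Receptor Signaling Pathway	0.046	3932	LCK	-0.24	0.025	0.875
T Cell Receptor Signaling Pathway	0.046	5788	PTPRC	-0.21	0.024	0.8675
T Cell Receptor Signaling Pathway	0.046	10892	MALT1	-0.43	0.015	0.905
T Cell Receptor Signaling Pathway	0.046	29851	ICOS	-0.41	0.018	0.915
Pancreatic Cancer	0.027	1021	CDK6	-0.48	0.010	0.955
Pancreatic Cancer	0.027	1869	E2F1	0.32	0.0015	1
Pancreatic Cancer	0.027	1870	E2F2	0.33	0.031	0.8375
Pancreatic Cancer	0.027	7042	TGFB2	-0.24	0.016	0.9325
Pancreatic Cancer	0.027	7422	VEGFA	0.15	0.031	0.83
Non Small Cell Lung Cancer	0.0095	1021	CDK6	-0.48	0.010	0.955
Non Small Cell Lung Cancer	0.0095	1869	E2F1	0.32	0.0015	1
Non Small Cell Lung Cancer	0.0095	1870	E2F2	0.33	0.031	0.8375
Non Small Cell Lung Cancer	0.0095	5579	PRKCB1	-0.39	0.021	0.8975
Non Small Cell Lung Cancer	0.0095	6256	RXRA	0.45	0.012	0.9525
Primary Immunodeficiency	0.0014	3561	IL2RG	-0.20	0.031	0.8125
Primary Immunodeficiency	0.0014	3575	IL7R	-0.23	0.0044	0.995
Primary Immunodeficiency	0.0014	3932	LCK	-0.24	0.025	0.875
Primary Immunodeficiency	0.0014	5788	PTPRC	-0.21	0.024	0.8675
Primary Immunodeficiency	0.0014	29851	ICOS	-0.41	0.018	0.915
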