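# MPeM-associated genes reported by nine genetic studies of malignant peritoneal mesothelioma
study	gene
Hung_2017_IHC_FISH_NGS	ALK
Joseph_2017_NGS510	ARID1A
Joseph_2017_NGS510	BAP1
Joseph_2017_NGS510	DDX3X
Joseph_2017_NGS510	NF2
Joseph_2017_NGS510	SETD2
Joseph_2017_NGS510	TERT
Joseph_2017_NGS510	WT1
Ugurluer_2016_NGS	AR
Ugurluer_2016_NGS	ASXL1
Ugurluer_2016_NGS	BAP1
Ugurluer_2016_NGS	BRIP1
Ugurluer_2016_NGS	CDK12
Ugurluer_2016_NGS	DAXX
Ugurluer_2016_NGS	EPHB1
Ugurluer_2016_NGS	ESR1
Ugurluer_2016_NGS	FGF6
Ugurluer_2016_NGS	IRS2
Ugurluer_2016_NGS	JAK1
Ugurluer_2016_NGS	KDM6A
Ugurluer_2016_NGS	KDR
Ugurluer_2016_NGS	KEAP1
Ugurluer_2016_NGS	KMT2A
Ugurluer_2016_NGS	MET
Ugurluer_2016_NGS	MRE11
Ugurluer_2016_NGS	MTOR
Ugurluer_2016_NGS	NSD1
Ugurluer_2016_NGS	SETD2
Ugurluer_2016_NGS	TSC1
Chirac_2016_CGH	ADAM3A
Chirac_2016_CGH	ARHGAP22
Chirac_2016_CGH	BAP1
Chirac_2016_CGH	CDH5
Chirac_2016_CGH	CDKN2A
Chirac_2016_CGH	CHEK2
Chirac_2016_CGH	CTNNB1
Chirac_2016_CGH	DPYD
Chirac_2016_CGH	EGFR
Chirac_2016_CGH	HRAS
Chirac_2016_CGH	IGKC
Chirac_2016_CGH	JUN
Chirac_2016_CGH	MAPK8
Chirac_2016_CGH	NF2
Chirac_2016_CGH	NR2F2
Chirac_2016_CGH	PTEN
Chirac_2016_CGH	RASSF1
Chirac_2016_CGH	RB1
Chirac_2016_CGH	RHEB
Chirac_2016_CGH	RICTOR
Chirac_2016_CGH	SDHB
Chirac_2016_CGH	SMARCB1
Chirac_2016_CGH	STK11
Chirac_2016_CGH	TRIO
Chirac_2016_CGH	VEGFB
Foster_2010_TKdomain	EGFR
Hung_2020_NGS_IHC	ARID1B
Hung_2020_NGS_IHC	BAP1
Hung_2020_NGS_IHC	CDKN2A
Hung_2020_NGS_IHC	CHEK2
Hung_2020_NGS_IHC	NF2
Hung_2020_NGS_IHC	PBRM1
Hung_2020_NGS_IHC	PRDM1
Hung_2020_NGS_IHC	SETD2
Hung_2020_NGS_IHC	SUZ12
Hung_2020_NGS_IHC	TP53
Hung_2020_NGS_IHC	TRAF7
Pillai_2013_IHC	MUC1
Varghese_2011_expression	PIK3CA
Varghese_2011_expression	RICTOR
Zaffaroni_2007_IHC	BIRC5
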