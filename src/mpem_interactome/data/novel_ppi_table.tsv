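# Per-seed-gene counts of known (n_known) and predicted novel (n_novel) PPIs,
# with the published list of predicted novel interactors per seed.
gene	n_known	n_novel	novel_partners
ADAM3A	0	0	
ALK	16	12	BIRC6,CLNS1A,DLG2,DNMT3A,HADHB,HMGB1,MSH2,NLRC4,RASA1,SMC1A,TSPAN16,TTC19
AR	265	0	
ARHGAP22	7	5	ALG11,GPRIN2,MAPK8,PTPN20,ZNF488
ARID1A	17	7	CDC123,EDEM1,GMEB1,SMPDL3B,TAF12,THEMIS2,VPS41
ARID1B	7	8	ARMT1,GINM1,MAU2,MTHFD1L,NCOA6,PLEKHG1,TNFRSF19,ZBTB2
ASXL1	6	9	DEFB115,DEFB116,FASN,ID1,IRAG1,MRPS7,NCOA6,POLD1,SRM
BAP1	27	2	PARP3,PLN
BIRC5	25	8	AANAT,AKAP6,CSNK1D,FASN,GCGR,NNMT,SSH2,TLE3
BRIP1	10	4	HPN,MRPS23,PATZ1,PECAM1
CDH5	21	7	CA7,CDH1,CDH16,CDH3,NQO1,PYGB,RND3
CDK12	9	9	AP1M2,CDKN1A,FNDC8,GSDMB,PCDHB14,PCNT,PDLIM7,RPL13,SLFN12
CDKN2A	168	5	CA9,DNAI1,GLIPR2,NFX1,SIT1
CHEK2	80	5	CRKL,FUS,GRK3,MN1,SUSD2
CTNNB1	187	11	ARHGEF4,ASGR2,CCR1,CDC25A,CDK5,GLUD1,GNAI2,LAMB2,PTPRB,SSTR3,TJP1
DAXX	113	10	ADGRF3,CDSN,COL11A2,DXO,FBXO25,GNL1,GTF2H4,H2BC15,IKBKE,NRG2
DDX3X	92	4	CETN2,GABRE,RABEP1,TBC1D25
DPYD	3	8	CPB2,CSDE1,HPCA,KCNJ4,OVGP1,RPS6KA3,SRC,SULT2A1
EGFR	409	4	HEBP1,PHKG1,POM121L12,STAG3L4
EPHB1	13	10	AADAC,ACP3,AMOTL2,CTPS1,GM2A,GTF2E1,MBD4,MRPL3,PCCB,UQCRC2
ESR1	365	6	DDX43,FNDC1,KATNA1,RPL27A,SPDEF,UST
FGF6	5	2	CELSR1,KLRC2
HRAS	146	7	C6ORF62,CCL4,HBG1,IGF2,INS,KCNQ1,ZFP36L2
IGKC	4	2	PLGLB2,REG3A
IRS2	40	10	CDKL1,CUL4A,EDEM1,LAMP1,MPO,NRAS,PROZ,PTPRR,RAP2A,SLC35B1
JAK1	72	8	ANKRD13C,CBR1,DAB1,DHX9,NFYC,P2RY1,P3H1,VNN2
JUN	180	9	DAB1,GART,GPR18,ISCU,NFYC,PML,ROR1,SNIP1,TACSTD2
KDM6A	11	7	AKAP4,BMP15,ELK1,HSD17B10,MAGED2,RBM3,ZNF157
KDR	60	8	ALB,CACNA1S,CHIC2,GSTA2,KIT,SHOX2,SRP72,UTP3
KEAP1	77	15	ADH5,ARPC1B,BNIP3L,CARM1,ERBIN,LONP1,PANX1,RTN4R,S1PR2,SDC1,SENP1,SLC5A5,VAC14,ZNF177,ZNF266
KMT2A	31	13	CKMT1A,DCTN1,EXOSC5,IL10RA,INPPL1,LAYN,MCTS1,PAFAH1B2,PLAAT4,PLPP2,RDX,TGFB2,VWA5A
MAPK8	137	8	ANXA8L1,ARHGAP22,CDC42,GDF10,GPRIN2,MT-CO1,PTPN20,TIMM23B
MET	112	12	CAMSAP3,CAV1,FOXA3,KCND2,KLK2,MRPL17,PABPC1,RASSF7,SH3KBP1,SLC26A3,SLC26A4,SND1-IT1
MRE11	20	8	CXCR5,DYNC1H1,ENDOD1,GPR83,JRKL,MLF2,TMEM126A
MTOR	52	7	CA6,MECR,NPPB,PIK3CD,SLC2A5,SLC45A1,SLC9A1
MUC1	134	12	ADGRL2,E2F2,GALE,IKBKE,LTB4R2,OAZ1,PKLR,PSMB4,RFX5,RPS24,SYT13,TFB2M
NF2	74	4	DRG1,LIF,OSM,PCNA
NR2F2	18	3	CHD2,RLBP1,SYCP3
NSD1	36	5	NPR3,PRKCD,RING1,RTN4,SNRPF
PBRM1	11	11	AMIGO3,B4GALT7,CCRL2,CELSR3,FBXW8,FDX1,HSD17B7,PCBP4,RFX3,SS18L2,TMIE
PIK3CA	70	8	ACOT8,ALCAM,CRIP1,LYPLA1,MAP3K9,PRKCI,RHOC,TRA2B
PRDM1	10	6	EXOSC3,FRK,HPGD,MAD2L1BP,MAN1A1,UTP18
PTEN	356	9	AKT3,ARL3,COL18A1,FGF7,KIF20B,LIPF,NCSTN,NR3C1,RBM15B
RASSF1	70	5	BANF1,LARS2,PFDN5,TMEM115,TMEM158
RB1	190	9	CDADC1,CNTN3,COX17,CRYBA4,CSK,ESD,LRCH1,MTRF1,PCDHB5
RHEB	29	6	CENPE,MAPK15,NOS3,PIGB,PPP1R3C,PTPRN2
RICTOR	11	8	ANXA10,C5ORF51,CTSW,IFT20,MROH2B,PHKB,PLCXD3,SIAH1
SDHB	6	9	CA6,FLOT1,MFAP2,RAP1GAP,RPL11,SLC45A1,SLC9A1,STMN1,TARBP1
SETD2	8	6	EXOSC7,GMPPB,KLHL18,NDUFAF3,TEX264,TMA7
SMARCB1	112	3	CNTNAP3,MYO18B,VPREB3
STK11	134	5	FAM98B,MADCAM1,PPP6R1,SH3GL1,ZNF195
SUZ12	17	9	ARHGAP5,CDK5R1,KLRC1,NOL4,NR1D1,PLA2G2A,RBBP4,SLC2A2,TBC1D29P
TERT	80	9	ATPAF2,EXOC3,HMGB2,ICE1,IFT57,IRS1,NDUFS6,PDCD6,PTMA
TP53	489	6	CARD14,CFHR3,MMP10,POLR2A,RCVRN,ZNF367
TRAF7	12	6	BTBD1,HAGHL,HDGF,NUDT16L1,PBXIP1,PPIC
TRIO	13	5	DAP,DNAH5,MARCHF6,NIPBL,PRMT7
TSC1	99	11	BRD3,CAPZA2,FCN1,FOLR2,NDUFA9,PAEP,PTPA,SLC16A6,TRAF2,TUBB4B,ZNF79
VEGFB	6	5	FOSL1,SF1,TFB1M,UCP2,UCP3
WT1	64	8	B3GNT3,BST2,CALML5,CAPRIN1,FJX1,HIPK3,PAX6,PEX3
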