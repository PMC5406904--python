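# Pathways over-represented in the 430-gene Alzheimer's disease gene set, with the
# disease-set member genes ("candidate genes") of each pathway, the raw Fisher
# exact-test p value and the Benjamini-Hochberg adjusted value.
# Columns: pathway_name <TAB> p_raw <TAB> p_bh <TAB> comma-joined candidate genes
Cytokines and inflammatory response	1.03e-9	8.79e-8	CXCL8,HLA-DRA,HLA-DRB1,IL10,IL12A,IL12B,IL1A,IL4,IL6,TGFB1,TNF
cytokine network	9.89e-9	3.84e-7	CXCL8,IL10,IL12A,IL12B,IL18,IL1A,IL4,IL6,TNF
Hematopoietic cell lineage	1.92e-7	5.46e-6	CD14,CD33,CD36,CD44,CR1,HLA-DRA,HLA-DRB1,HLA-DRB5,IL1A,IL1B,IL4,IL6,IL6R,MME,TNF
Dendritic cells in regulating TH1 and TH2 Development	3.11e-7	8.29e-6	CD33,IL10,IL12A,IL12B,IL4,TLR2,TLR4,TLR9
Ovarian steroidogenesis	5.88e-6	1.09e-4	ALOX5,CYP19A1,FSHR,IGF1,INS,LDLR,LHCGR,PLA2G4A,PTGS2,STAR
IL-5 signaling pathway	9.00e-6	1.60e-4	HLA-DRA,HLA-DRB1,IL1B,IL4,IL6
Neurotrophin signaling pathway	1.08e-5	1.77e-4	BDNF,CAMK2D,GSK3B,IRS1,NGF,NGFR,NTF3,NTRK1,NTRK2,PIK3R1,PSEN1,PSEN2,SOS2,TP53,TP73
HIF-1 signaling pathway	1.12e-5	1.77e-4	CAMK2D,EIF4EBP1,GAPDH,HMOX1,IGF1,IL6,IL6R,INS,NOS3,PIK3R1,RPS6KB2,TF,TLR4,VEGFA
NOD-like receptor signaling pathway	1.66e-5	2.37e-4	CARD8,CCL2,CXCL8,IL18,IL1B,IL6,MEFV,NLRP1,NLRP3,TNF
Mechanism of gene regulation by peroxisome proliferators via PPARα	1.95e-5	2.69e-4	APOA1,CD36,INS,LPL,PIK3R1,PPARA,PTGS2,RXRA,SP1,TNF
Th1/Th2 differentiation	2.54e-5	3.19e-4	HLA-DRA,HLA-DRB1,IL12A,IL12B,IL18,IL4
Antigen-dependent B-cell activation	2.68e-5	3.26e-4	FAS,HLA-DRA,HLA-DRB1,IL10,IL4
Oxidative phosphorylation	3.74e-5	4.39e-4	COX10,COX15,MT-ATP6,MT-ATP8,MT-CO1,MT-CO2,MT-CO3,MT-CYB,MT-ND1,MT-ND2,MT-ND3,MT-ND4,MT-ND4L,MT-ND5,MT-ND6
PI3K-Akt signaling pathway	3.80e-5	4.39e-4	COL11A1,EFNA5,EIF4EBP1,FGF1,GNB3,GSK3B,IGF1,IL4,IL6,IL6R,INS,IRS1,NGF,NGFR,NOS3,PCK1,PIK3R1,PPP2R2B,RELN,RPS6KB2,RXRA,SOS2,TLR2,TLR4,TP53,VEGFA,YWHAQ
NF-κB signaling pathway	4.83e-5	5.42e-4	CD14,CXCL8,ICAM1,IL1B,LCK,PARP1,PLAU,PTGS2,TLR4,TNF,TRAF2,UBE2I
Phagosome	7.77e-5	8.29e-4	CD14,CD36,CTSS,HLA-A,HLA-DQB1,HLA-DRA,HLA-DRB1,HLA-DRB5,MBL2,MPO,NOS1,OLR1,RAB7A,TAP2,TLR2,TLR4
Erythrocyte differentiation pathway	9.33e-5	9.49e-4	CCL3,IGF1,IL1A,IL6,TGFB1
IL-10 anti-inflammatory signaling pathway	1.82e-4	1.69e-3	HMOX1,IL10,IL1A,IL6,TNF
Cells and molecules involved in local acute inflammatory response	1.82e-4	1.69e-3	CXCL8,ICAM1,IL1A,IL6,TNF
Toll-like receptor signaling pathway	2.15e-4	1.95e-3	CCL3,CD14,CXCL8,IL12A,IL12B,IL1B,IL6,PIK3R1,TLR2,TLR4,TLR9,TNF
Free radical induced apoptosis	2.22e-4	1.97e-3	CXCL8,GPX1,SOD1,TNF
Intestinal immune network for IgA production	2.65e-4	2.26e-3	HLA-DQB1,HLA-DRA,HLA-DRB1,HLA-DRB5,IL10,IL4,IL6,TGFB1
Selective expression of chemokine receptors during T-cell polarization	3.35e-4	2.68e-3	CCL3,CCR2,IL12A,IL12B,IL4,TGFB1
B lymphocyte cell surface molecules	3.39e-4	2.68e-3	CR1,HLA-DRA,HLA-DRB1,ICAM1
Phosphorylation of MEK1 by cdk5/p35 downregulates the MAP kinase pathway	3.39e-4	2.68e-3	CDK5,CDK5R1,NGF,NGFR
Complement and coagulation cascades	4.61e-4	3.58e-3	A2M,C4A,C4B,CFH,CR1,F13A1,MBL2,PLAU,SERPINA1
ABC transporters	5.87e-4	4.32e-3	ABCA1,ABCA2,ABCA7,ABCC2,ABCG1,ABCG2,TAP2
Signal transduction through IL-1R	6.97e-4	5.05e-3	IL1A,IL1B,IL1RN,IL6,TGFB1,TNF
mTOR signaling pathway	8.19e-4	5.83e-3	EIF4EBP1,IGF1,INS,IRS1,PIK3R1,RPS6KB2,TNF,VEGFA
Adhesion and diapedesis of granulocytes	9.49e-4	6.65e-3	CXCL8,ICAM1,IL1A,TNF
TNF signaling pathway	1.12e-3	7.69e-3	CCL2,FAS,ICAM1,IL1B,IL6,MAGI2,MMP3,PIK3R1,PTGS2,TNF,TRAF2
MAPK signaling pathway	1.13e-3	7.69e-3	BDNF,CD14,FAS,FGF1,IL1A,IL1B,MAPK8IP1,MAPT,MEF2C,NGF,NTF3,NTRK1,NTRK2,PLA2G4A,SOS2,TGFB1,TNF,TP53,TRAF2
The IGF-1 receptor and longevity	1.26e-3	8.28e-3	IGF1,PIK3R1,SOD1,SOD2
Glutathione metabolism	1.45e-3	8.95e-3	GPX1,GSTM1,GSTM3,GSTO1,GSTO2,GSTP1,GSTT1
Cytokine–cytokine receptor interaction	1.48e-3	8.95e-3	CCL2,CCL3,CCR2,CXCL8,FAS,IL10,IL12A,IL12B,IL18,IL1A,IL1B,IL23R,IL4,IL6,IL6R,NGFR,TGFB1,TNF,VEGFA
Serotonergic synapse	1.50e-3	8.95e-3	ALOX5,APP,CYP2D6,GNB3,HTR2A,HTR6,KCNJ6,MAOA,PLA2G4A,PTGS2,SLC6A4
Antigen processing and presentation	1.63e-3	9.53e-3	CTSS,HLA-A,HLA-DQB1,HLA-DRA,HLA-DRB1,HLA-DRB5,HSPA5,TAP2,TNF
Drug metabolism—cytochrome P450	1.88e-3	1.05e-2	CYP2D6,GSTM1,GSTM3,GSTO1,GSTO2,GSTP1,GSTT1,MAOA
Cell cycle: G1/S check point	2.13e-3	1.18e-2	CDK1,CDKN2A,GSK3B,TGFB1,TP53
Fcε RI signaling pathway	2.26e-3	1.23e-2	FCER1G,GAB2,IL4,INPP5D,PIK3R1,PLA2G4A,SOS2,TNF
Apoptosis	2.28e-3	1.23e-2	FAS,IL1A,IL1B,NGF,NTRK1,PIK3R1,TNF,TP53,TRAF2
Role of Erk5 in neuronal survival	2.61e-3	1.39e-2	MEF2A,MEF2C,NTRK1,PIK3R1
Bioactive peptide-induced signaling pathway	2.90e-3	1.52e-2	CAMK2D,CDK5,GNA11,MAPT,MYLK,PTK2B
Control of skeletal myogenesis by HDAC and calcium/calmodulin-dependent kinase (CaMK)	2.93e-3	1.52e-2	IGF1,INS,MEF2A,MEF2C,PIK3R1
Metabolism of xenobiotics by cytochrome P450	3.22e-3	1.62e-2	CYP2D6,GSTM1,GSTM3,GSTO1,GSTO2,GSTP1,GSTT1,HSD11B1
Ras-independent pathway in NK cell-mediated cytotoxicity	3.92e-3	1.88e-2	HLA-A,IL18,PIK3R1,PTK2B
Dopaminergic synapse	4.48e-3	2.11e-2	CAMK2D,CLOCK,COMT,DRD4,GNB3,GRIN2B,GSK3B,KCNJ6,MAOA,PPP2R2B,SLC6A3
Cholinergic synapse	4.57e-3	2.12e-2	CAMK2D,CHAT,CHRNA3,CHRNA4,CHRNA7,CHRNB2,GNA11,GNB3,KCNJ6,PIK3R1
The co-stimulatory signal during T-cell activation	4.72e-3	2.17e-2	HLA-DRA,HLA-DRB1,LCK,PIK3R1
Adhesion and diapedesis of lymphocytes	5.03e-3	2.28e-2	CXCL8,ICAM1,IL1A
Notch signaling pathway	5.07e-3	2.28e-2	APH1A,APH1B,NCSTN,PSEN1,PSEN2,PSENEN
Role of ERBB2 in signal transduction and oncology	5.61e-3	2.50e-2	ESR1,IL6,IL6R,PIK3R1
Aminoacyl-tRNA biosynthesis	6.37e-3	2.80e-2	MT-TG,MT-TH,MT-TL2,MT-TQ,MT-TR,MT-TS2,MT-TT
Trka receptor signaling pathway	6.55e-3	2.80e-2	NGF,NTRK1,PIK3R1
Rac 1 cell motility signaling pathway	6.62e-3	2.80e-2	CDK5,CDK5R1,MYLK,PIK3R1
CTCF: first multivalent nuclear factor	6.62e-3	2.80e-2	CDKN2A,PIK3R1,TGFB1,TP53
Regulation of PGC-1a	7.74e-3	3.21e-2	CAMK2D,MEF2A,MEF2C,PPARA
Calcium signaling pathway	7.85e-3	3.22e-2	ADRB1,ADRB2,ADRB3,CAMK2D,CHRNA7,GNA11,HTR2A,HTR6,LHCGR,MYLK,NOS1,NOS3,PTK2B
Lck and Fyn tyrosine kinases in initiation of TCR activation	8.30e-3	3.38e-2	HLA-DRA,HLA-DRB1,LCK
Adipocytokine signaling pathway	8.75e-3	3.52e-2	CD36,IRS1,PCK1,PPARA,RXRA,TNF,TRAF2
Ras signaling pathway	9.43e-3	3.76e-2	EFNA5,EXOC2,FGF1,GAB2,GNB3,GRIN2B,IGF1,INS,NGF,NGFR,PIK3R1,PLA2G3,PLA2G4A,SOS2,VEGFA
Prolactin signaling pathway	1.02e-2	3.96e-2	ESR1,ESR2,GSK3B,INS,LHCGR,PIK3R1,SOS2
Catecholamine biosynthesis, tyrosine->dopamine->noradrenaline->adrenaline	1.05e-2	3.99e-2	DBH,PNMT
Fat digestion and absorption	1.14e-2	4.32e-2	ABCA1,APOA1,APOA4,CD36,PLA2G3
Stress induction of HSP regulation	1.26e-2	4.63e-2	FAS,IL1A,TNF
Regulation of hematopoiesis by cytokines	1.26e-2	4.63e-2	CXCL8,IL4,IL6
CTL-mediated immune response against target cells	1.26e-2	4.63e-2	FAS,HLA-A,ICAM1
Osteoclast differentiation	1.32e-2	4.81e-2	GAB2,IL1A,IL1B,LCK,PIK3R1,PPARG,TGFB1,TNF,TRAF2,TREM2
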