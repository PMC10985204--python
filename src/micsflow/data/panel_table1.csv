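Antigen,Clone,Dilution,OrderNo,Fluorochrome,Company
Actin (smooth muscle),REAL650,50,130-123-363,FITC,Miltenyi Biotec
AFP,C3,50,sc-8399PE,PE,Santa Cruz Biotechnology
B7-H4,MIH43,100,358104,PE,BioLegend
Bcl-2,REA872,50,130-114-230,FITC,Miltenyi Biotec
Bcl-xL,H-5,200,Sc-8392PE,PE,Santa Cruz Biotechnology
CCL18,REA487,50,130-107-608,PE,Miltenyi Biotec
CD10,REAL318,50,130-118-368,FITC,Miltenyi Biotec
CD105,REA794,50,130-112-169,FITC,Miltenyi Biotec
CD107a,REA792,50,130-111-620,FITC,Miltenyi Biotec
CD112,REA1195,50,130-122-770,PE,Miltenyi Biotec
CD117,REA787,50,130-111-592,PE (APC),Miltenyi Biotec
CD11a,REA378,50,130-124-886,FITC,Miltenyi Biotec
CD11b,REA713,50,130-110-552,FITC,Miltenyi Biotec
CD11c,REA618,50,130-113-587,PE,Miltenyi Biotec
CD123,REA918,50,130-115-263,FITC (APC),Miltenyi Biotec
CD133,REA820,50,130-112-195,PE,Miltenyi Biotec
CD138,REA929,50,130-115-479,PE (APC),Miltenyi Biotec
CD146,REA773,50,130-111-322,PE,Miltenyi Biotec
CD15,VIMC6,50,130-113-484,FITC,Miltenyi Biotec
CD155,REA1081,50,130-118-998,PE,Miltenyi Biotec
CD163,REA812,50,130-112-132,FITC,Miltenyi Biotec
CD169,REA1176,50,130-121-106,PE,Miltenyi Biotec
CD171,L1-OV198.5,200,371604,PE,BioLegend
CD183,REA232,50,130-120-452,PE,Miltenyi Biotec
CD184,REA649,50,130-117-504,PE,Miltenyi Biotec
CD19,LT19,50,130-113-168,FITC,Miltenyi Biotec
CD196,REA190,50,130-120-458,PE,Miltenyi Biotec
CD1c,AD5-8E7,50,130-113-301,FITC,Miltenyi Biotec
CD2,REA1130,50,130-119-508,PE,Miltenyi Biotec
CD20,REA1087,50,130-118-292,FITC (PE),Miltenyi Biotec
CD200,REA1067,50,130-118-128,FITC,Miltenyi Biotec
CD206,DCN228,50,130-123-671,FITC (PE),Miltenyi Biotec
CD21,REA940,50,130-115-609,FITC,Miltenyi Biotec
CD22,REA340,50,130-124-223,FITC,Miltenyi Biotec
CD24,REA832,50,130-112-656,PE,Miltenyi Biotec
CD243,REA495,50,130-124-440,PE (APC),Miltenyi Biotec
CD25,REA945,50,130-115-534,PE (APC),Miltenyi Biotec
CD25,M-A251,50,356104,PE,BioLegend
CD26,FR10-11G9,50,130-126-362,PE,Miltenyi Biotec
CD27,REA499,50,130-113-639,FITC (PE),Miltenyi Biotec
CD276,REA1094,50,130-118-570,PE (FITC),Miltenyi Biotec
CD3,REA1151,50,130-120-267,FITC (APC),Miltenyi Biotec
CD31,REA1028,50,130-117-224,FITC,Miltenyi Biotec
CD314,REA1228,50,130-124-341,PE,Miltenyi Biotec
CD34,REA1164,50,130-120-515,PE,Miltenyi Biotec
CD36,REA760,50,130-110-739,FITC,Miltenyi Biotec
CD38,REA671,50,130-117-717,PE (APC),Miltenyi Biotec
CD39,REA739,50,130-110-650,PE,Miltenyi Biotec
CD4,REA623,50,130-114-531,FITC (PE),Miltenyi Biotec
CD40,REA733,50,130-110-946,PE,Miltenyi Biotec
CD44,REA690,50,130-113-342,PE (FITC),Miltenyi Biotec
CD45,REA747,50,130-110-632,PE,Miltenyi Biotec
CD45RA,T6D11,50,130-113-355,FITC,Miltenyi Biotec
CD45RO,UCHL1,50,130-113-549,FITC,Miltenyi Biotec
CD47,REA220,50,130-123-754,PE,Miltenyi Biotec
CD48,REA426,50,130-106-516,PE,Miltenyi Biotec
CD49α,REA1106,11,130-119-305,FITC,Miltenyi Biotec
CD49β,REA188,11,130-100-337,FITC,Miltenyi Biotec
CD54,REA266,50,130-120-711,PE,Miltenyi Biotec
CD56,AF12-7H3,50,130-113-307,PE (APC),Miltenyi Biotec
CD57,REA769,50,130-111-810,PE,Miltenyi Biotec
CD61,REA761,50,130-110-748,FITC,Miltenyi Biotec
CD64,REA987,50,130-116-195,FITC,Miltenyi Biotec
CD66b,REA306,50,130-123-694,FITC,Miltenyi Biotec
CD69,FN50,50,130-113-524,FITC (PE),Miltenyi Biotec
CD70,REA292,100,130-104-307,FITC,Miltenyi Biotec
CD71,REA902,50,130-115-028,FITC (PE),Miltenyi Biotec
CD73,REA804,50,130-111-908,PE (APC),Miltenyi Biotec
CD74,REA1103,50,130-119-026,PE,Miltenyi Biotec
CD8,REA734,50,130-110-677,FITC,Miltenyi Biotec
CD9,REA1071,50,130-118-806,FITC,Miltenyi Biotec
CD90,REA897,50,130-114-859,FITC,Miltenyi Biotec
CD95,REA738,50,130-113-004,PE (FITC),Miltenyi Biotec
CD96,REA195,100,130-101-032,PE,Miltenyi Biotec
CD99,REA1174,50,130-121-078,PE,Miltenyi Biotec
Collagen III,REAL912,50,130-127-357,PE,Miltenyi Biotec
Collagen IV,REAL567,50,130-122-866,PE,Miltenyi Biotec
CSF1R,12-3A3-1B10,100,NBP1-43362PE,PE,Novus Biologicals
CTLA-4,BNI3,200,369604,PE,BioLegend
Desmin,REA1134,50,130-119-489,"FITC (APC, PE)",Miltenyi Biotec
EpCAM,REA764,50,130-110-998,FITC,Miltenyi Biotec
Fibronectin,REAL555,50,130-122-864,PE,Miltenyi Biotec
FOLR2,NBP2-99741,100,NBP2-99741F,FITC,Novus Biologicals
FoxP3,236A/E7,50,12-4777-42,PE,Thermo Fisher Scientific
FSP-1,NBP2-36431,200,NBP2-36431F,FITC,Novus Biologicals
Galectin 9,REA435,50,130-124-237,PE (APC),Miltenyi Biotec
GD2,14.G2a,50,562100,PE (FITC),BD
GFAP,REA335,50,130-118-351,PE,Miltenyi Biotec
Glypican 3,307801,200,FAB2119G,FITC,RnD Systems
H2AX,REA502,50,130-125-883,PE,Miltenyi Biotec
HER2,REA1232,50,130-124-466,PE,Miltenyi Biotec
HIF-1,EP1215Y,200,ab190197,FITC,Abcam
HLA-ABC,REA230,50,130-120-055,"PE (APC, FITC)",Miltenyi Biotec
HLA-DR,REA805,50,130-111-789,"PE (APC, FITC)",Miltenyi Biotec
HLA-DR/DP/DQ,REA332,50,130-120-715,PE,Miltenyi Biotec
HNF-4α,H-1,50,sc-374229PE,PE,Santa Cruz Biotechnology
Hsp70,REA349,50,130-124-694,FITC,Miltenyi Biotec
IDO,D5J4E,100,103125,PE,Cell Signaling Technology
Ki-67,REA183,50,130-117-691,FITC,Miltenyi Biotec
LAG3,REA351,25,130-120-470,PE,Miltenyi Biotec
MUC1,16A,50,355604,PE,BioLegend
Myosin,REA1107,100,130-119-313,FITC,Miltenyi Biotec
NANOG,REA314,50,130-117-377,PE,Miltenyi Biotec
p16,F-12,50,sc-1661PE,PE,Santa Cruz Biotechnology
p21,F-8,50,sc-271610PE,PE,Santa Cruz Biotechnology
p53,REA1132,50,130-119-502,PE,Miltenyi Biotec
Pan-Cytokeratin,REA831,50,130-112-743,"FITC (APC, PE)",Miltenyi Biotec
PD-1,REA1165,50,130-120-382,PE,Miltenyi Biotec
PDGFR β,MAB1263,200,FAB1263T-100UG,FITC,RnD Systems
PD-L1 1,REA1197,50,130-122-809,PE,Miltenyi Biotec
PD-L1 2,MIH2,50,393608,PE,BioLegend
Podoplanin,REAL468,50,130-125-009,FITC,Miltenyi Biotec
PSMA,GCP-04,100,NBP1-45057AF488,FITC,Novus Biologicals
S100A8,REA917,50,130-115-253,"FITC (APC, PE)",Miltenyi Biotec
S100A9,REA859,50,130-114-515,FITC,Miltenyi Biotec
SSEA-1 (CD15),REA321,50,130-117-689,PE,Miltenyi Biotec
TIM3,REAL818,50,130-125-682,PE,Miltenyi Biotec
Vimentin,REA409,50,130-123-774,"PE (APC, FITC)",Miltenyi Biotec
VISTA,D1L2G,200,18946,PE,Cell Signaling Technology
β-Actin,REA1148,50,130-120-276,FITC,Miltenyi Biotec
β-Catenin,REA480,50,130-123-546,"FITC (APC, PE)",Miltenyi Biotec
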