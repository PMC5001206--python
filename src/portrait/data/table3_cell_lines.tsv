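cell_line	gender	hist_subtype	source	er	pr	her2	pam50	final_classification
AU565	F		ATCC	-	-	+	Her2amp	Her2amp
BT-20	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
BT-474	F	ductal_carcinoma	ATCC	+	+	+	Luminal B	Luminal B
BT-483	F	ductal_carcinoma	ATCC	+	+	-	Luminal A	Luminal A
BT-549	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
CAL-120	F		DSMZ	-	-	-	Basal-like	Basal-like
CAL-148	F	ductal_carcinoma	DSMZ	-	-	-	Luminal B	Basal-like
CAL-51	F		DSMZ	-	-	-	Basal-like	Basal-like
CAL-85-1	F		DSMZ	-	-	-	Basal-like	Basal-like
CAMA-1	F		ATCC	+	-	-	Luminal B	Luminal A
DU4475	F		ATCC	-	-	-	Basal-like	Basal-like
EFM-19	F	ductal_carcinoma	DSMZ	+	+	-	Luminal B	Luminal A
EFM-192A	F		DSMZ	+	-	+	Her2amp	Luminal B
EVSA-T	F		DSMZ	+	-	+	NON	Luminal B
HCC1143	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
HCC1187	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
HCC1395	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
HCC1419	F	ductal_carcinoma	ATCC	-	-	+	Her2amp	Her2amp
HCC1428	F		ATCC	+	+	-	Luminal B	Luminal A
HCC1500	F	ductal_carcinoma	ATCC	-	-	-	Luminal A	Basal-like
HCC1569	F	metaplastic_carcinoma	ATCC	-	-	+	Basal-like	Her2amp
HCC1599	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
HCC1806	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
HCC1937	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
HCC1954	F	ductal_carcinoma	ATCC	-	-	+	Her2amp	Her2amp
HCC202	F	ductal_carcinoma	ATCC	-	-	+	Her2amp	Her2amp
HCC2157	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
HCC2218	F	ductal_carcinoma	ATCC	-	-	+	Luminal A	Her2amp
HCC38	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
HCC70	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
HDQ-P1	F	ductal_carcinoma	DSMZ	-	-	-	Basal-like	Basal-like
HMC-1-8	F		HSRRB				NON	Luminal A
Hs 274.T	F		ATCC				Basal-like	Luminal B
Hs 281.T	F		ATCC				Basal-like	Her2amp
Hs 343.T	F		ATCC				Basal-like	Her2amp
Hs 578 T	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
Hs 606.T	F		ATCC				Luminal A	Luminal B
Hs 739.T	F		ATCC				Basal-like	Basal-like
Hs 742.T	F		ATCC				Luminal A	Luminal A
JIMT-1	F	ductal_carcinoma	DSMZ	-	-		Basal-like	Her2amp
KPL-1	F	ductal_carcinoma	DSMZ				Luminal A	Basal-like
MCF7	F		ATCC	+	+	-	Luminal A	Luminal A
MDA-MB-134-VI	F	ductal_carcinoma	ATCC	+	-		Luminal A	Luminal A
MDA-MB-157	F	ductal_carcinoma	ATCC	-	-	-	Basal-like	Basal-like
MDA-MB-175-VII	F	ductal_carcinoma	ATCC	+	-		Luminal B	Luminal A
MDA-MB-231	F		ATCC	-	-		Basal-like	Basal-like
MDA-MB-361	F		ATCC	+	+	+	Luminal B	Luminal B
MDA-MB-415	F		ATCC	+	-	-	Luminal B	Luminal A
MDA-MB-436	F		ATCC	-	-	-	Basal-like	Basal-like
MDA-MB-453	F		ATCC	-	-	-	Luminal B	Her2amp
MDA-MB-468	F		ATCC	-	-	-	Basal-like	Basal-like
SK-BR-3	F		ATCC	-	-	+	Her2amp	Her2amp
T-47D	F	ductal_carcinoma	ATCC	+	+	-	Luminal B	Luminal A
UACC-812	F	ductal_carcinoma	ATCC	+	-	+	Her2amp	Luminal B
UACC-893	F	ductal_carcinoma	ATCC	-	-	+	Her2amp	Her2amp
YMB-1	F		HSRRB	+	-	-	Luminal B	Luminal A
ZR-75-1	F	ductal_carcinoma	ATCC				Luminal A	Her2amp
ZR-75-30	F	ductal_carcinoma	ATCC	+	+	-	Her2amp	Luminal A
HCC2185				-	-	-	NON	Basal-like
HMEL							NON	Basal-like
HCC3153				-	-	-	NON	Basal-like
ZR75B				+	-	-	NON	Luminal A
600MPE				+	-	-	NON	Luminal A
SUM1315MO2				-	-		NON	Basal-like
SUM149PT				-	-	-	NON	Basal-like
SUM159PT				-	-	-	NON	Basal-like
SUM225CWN				-	-	+	NON	Her2amp
LY2				+	-	-	NON	Luminal A
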