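# Reported per-gene results (MIS and permutation p-value, 1000 permutations)
# for disease genes significant at p < 0.05 in the four top-ranked OMIM
# disease classes of the original STRING-v10 obesity-gene analysis that this
# package reimplements.  p-values printed as "<0.001" are exact zeros on the
# Lambda/1000 grid and are recorded as 0.000.
disease_class	gene_symbol	mis	p_value
Nutritional	UCP1	969	0.000
Nutritional	POMC	998	0.000
Nutritional	PPARG	999	0.000
Nutritional	AGRP	999	0.000
Nutritional	MC4R	999	0.000
Nutritional	PCSK1	970	0.000
Nutritional	PPARGC1B	978	0.000
Nutritional	UCP3	960	0.000
Nutritional	GHRL	994	0.000
Nutritional	ADRB3	964	0.000
Nutritional	PYY	993	0.000
Nutritional	ENPP1	979	0.000
Nutritional	NR0B2	993	0.027
Nutritional	SIM1	879	0.044
Nutritional	HTR2A	949	0.046
Endocrine	RETN	981	0.000
Endocrine	PPP1R3A	954	0.000
Endocrine	NEUROD1	994	0.000
Endocrine	MC2R	998	0.000
Endocrine	CYP17A1	994	0.000
Endocrine	AVP	997	0.000
Endocrine	INS	999	0.000
Endocrine	PPARG	999	0.000
Endocrine	LIPC	984	0.000
Endocrine	AVPR2	804	0.000
Endocrine	PTPN1	999	0.000
Endocrine	IGF2BP2	989	0.000
Endocrine	FSHB	999	0.000
Endocrine	CYP11B1	973	0.000
Endocrine	IRS1	999	0.000
Endocrine	KCNJ11	999	0.000
Endocrine	AR	999	0.000
Endocrine	ABCC8	999	0.000
Endocrine	IL6	999	0.000
Endocrine	STAT5B	999	0.000
Endocrine	HNF4A	999	0.000
Endocrine	ENPP1	979	0.000
Endocrine	IRS2	999	0.000
Endocrine	CAPN10	923	0.000
Endocrine	SSTR5	968	0.013
Endocrine	PAX8	954	0.014
Endocrine	GCK	989	0.017
Endocrine	TBX19	937	0.017
Endocrine	TSHR	980	0.017
Endocrine	SLC2A4	994	0.026
Endocrine	PAX4	925	0.030
Endocrine	STAR	942	0.032
Endocrine	HGF	992	0.033
Endocrine	BMP15	699	0.034
Endocrine	HNF1A	993	0.036
Endocrine	GPD2	924	0.038
Endocrine	HMGA1	984	0.041
Endocrine	GCGR	960	0.043
Psychiatric	DRD4	972	0.000
Psychiatric	SLC6A4	961	0.000
Psychiatric	AKT1	999	0.000
Psychiatric	APOL4	742	0.000
Psychiatric	COMT	981	0.000
Psychiatric	BDNF	999	0.000
Psychiatric	SLC6A3	984	0.017
Psychiatric	CHI3L1	842	0.024
Psychiatric	APOL2	662	0.035
Psychiatric	HCRT	967	0.043
Psychiatric	HTR2A	949	0.046
Bone	ALPL	969	0.000
Bone	ANKH	610	0.015
Bone	TNFRSF11B	895	0.034
Bone	EXT1	968	0.043
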