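region_a	region_b	r_nc	r_ad	t	reported_class
ENT_L	INS_R	0.8	0.42	4.49	decrease-positive
ENT_L	BSTS_R	0.86	0.5	4.39	decrease-positive
ENT_L	CMF_R	0.64	0.18	3.58	decrease-positive
TP_L	POPE_R	0.83	0.71	3.22	decrease-positive
ENT_L	PARC_L	0.56	0.22	2.75	decrease-positive
ENT_L	POPE_R	0.86	0.67	2.54	decrease-positive
POPE_R	TP_R	0.79	0.69	2.41	decrease-positive
ENT_L	POPE_L	0.79	0.45	2.37	decrease-positive
MT_R	PSTC_R	0.3	0.02	2.24	decrease-positive
MT_R	SF_R	0.59	0.31	2.24	decrease-positive
ENT_L	TT_L	0.71	0.4	2.15	decrease-positive
ENT_L	ENT_R	0.97	0.83	2.05	decrease-positive
MT_R	PCUN_R	0.33	0.12	1.78	decrease-positive
MT_R	SP_R	0.36	0.16	1.43	decrease-positive
MT_R	PREC_R	0.37	0.21	1.11	decrease-positive
MT_R	RMF_R	0.24	0.12	0.86	decrease-positive
MT_R	SMAR_R	0.49	0.4	0.81	decrease-positive
ENT_L	LOCC_L	-0.97	-0.8	-4.65	decrease-negative
CUN_L	ENT_L	-0.59	-0.26	-4.25	decrease-negative
ENT_L	LING_L	-0.89	-0.62	-3.71	decrease-negative
SF_L	MOF_R	-0.73	-0.38	-3.54	decrease-negative
POPE_R	SP_R	-0.73	-0.49	-3.19	decrease-negative
ENT_L	CUN_R	-0.55	-0.26	-3.07	decrease-negative
ENT_L	LING_R	-0.85	-0.54	-2.93	decrease-negative
MT_R	RAC_R	-0.32	-0.04	-2.68	decrease-negative
POPE_R	PREC_R	-0.4	-0.1	-2.68	decrease-negative
ENT_L	PERI_L	-0.75	-0.45	-2.64	decrease-negative
POPE_R	PSTC_R	-0.66	-0.48	-2.54	decrease-negative
ENT_L	LOCC_R	-0.93	-0.79	-2.24	decrease-negative
ENT_L	PERI_R	-0.75	-0.51	-2.15	decrease-negative
MT_R	FP_R	-0.44	-0.25	-1.90	decrease-negative
MT_R	PORB_R	-0.42	-0.19	-1.63	decrease-negative
MT_R	TP_R	-0.15	0.05	-1.20	decrease-negative
MT_R	TT_R	-0.14	-0.06	-0.89	decrease-negative
ENT_L	FP_L	0.25	0.58	-4.02	increase-positive
ENT_L	FP_R	0.3	0.59	-3.50	increase-positive
ENT_L	PORB_L	0.48	0.67	-3.07	increase-positive
ENT_L	PC_L	0.29	0.61	-2.93	increase-positive
ENT_L	PORB_R	0.51	0.72	-2.68	increase-positive
ENT_L	MOF_L	-0.15	0.15	-2.24	increase-positive
MT_R	POPE_R	-0.04	0.19	-2.21	increase-positive
LOF_L	FUSI_R	-0.04	0.05	-0.43	increase-positive
MT_R	INS_R	0.17	0.21	-0.29	increase-positive
ENT_L	PREC_L	-0.29	-0.55	3.97	increase-negative
ENT_L	SF_L	-0.45	-0.63	3.97	increase-negative
ENT_L	ST_R	0.06	-0.29	3.54	increase-negative
ENT_L	SF_R	-0.49	-0.67	3.19	increase-negative
ENT_L	ST_L	0.06	-0.30	3.07	increase-negative
ENT_L	PREC_R	-0.34	-0.56	2.96	increase-negative
ENT_L	SP_L	-0.75	-0.79	2.15	increase-negative
ENT_L	SMAR_R	-0.42	-0.58	2.09	increase-negative
ENT_L	SMAR_L	-0.42	-0.62	2.05	increase-negative
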