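name	abbrev	hemisphere	lobe	class
lh_bankssts	BSTS_L	L	temporal	association
lh_caudalanteriorcingulate	CAC_L	L	cingulate	paralimbic
lh_caudalmiddlefrontal	CMF_L	L	frontal	association
lh_cuneus	CUN_L	L	occipital	association
lh_entorhinal	ENT_L	L	temporal	association
lh_frontalpole	FP_L	L	frontal	association
lh_fusiform	FUSI_L	L	temporal	association
lh_inferiorparietal	IP_L	L	parietal	association
lh_inferiortemporal	IT_L	L	temporal	association
lh_insula	INS_L	L	insula	paralimbic
lh_isthmuscingulate	IC_L	L	cingulate	paralimbic
lh_lateraloccipital	LOCC_L	L	occipital	association
lh_lateralorbitofrontal	LOF_L	L	frontal	paralimbic
lh_lingual	LING_L	L	occipital	association
lh_medialorbitofrontal	MOF_L	L	frontal	paralimbic
lh_middletemporal	MT_L	L	temporal	association
lh_paracentral	PARC_L	L	frontal	association
lh_parahippocampal	PARH_L	L	temporal	paralimbic
lh_parsopercularis	POPE_L	L	frontal	association
lh_parsorbitalis	PORB_L	L	frontal	association
lh_parstriangularis	PTRI_L	L	frontal	association
lh_pericalcarine	PERI_L	L	occipital	primary
lh_postcentral	PSTC_L	L	parietal	primary
lh_posteriorcingulate	PC_L	L	cingulate	paralimbic
lh_precentral	PREC_L	L	frontal	primary
lh_precuneus	PCUN_L	L	parietal	association
lh_rostralanteriorcingulate	RAC_L	L	cingulate	paralimbic
lh_rostralmiddlefrontal	RMF_L	L	frontal	association
lh_superiorfrontal	SF_L	L	frontal	association
lh_superiorparietal	SP_L	L	parietal	association
lh_superiortemporal	ST_L	L	temporal	association
lh_supramarginal	SMAR_L	L	parietal	association
lh_temporalpole	TP_L	L	temporal	association
lh_transversetemporal	TT_L	L	temporal	primary
rh_bankssts	BSTS_R	R	temporal	association
rh_caudalanteriorcingulate	CAC_R	R	cingulate	paralimbic
rh_caudalmiddlefrontal	CMF_R	R	frontal	association
rh_cuneus	CUN_R	R	occipital	association
rh_entorhinal	ENT_R	R	temporal	association
rh_frontalpole	FP_R	R	frontal	association
rh_fusiform	FUSI_R	R	temporal	association
rh_inferiorparietal	IP_R	R	parietal	association
rh_inferiortemporal	IT_R	R	temporal	association
rh_insula	INS_R	R	insula	paralimbic
rh_isthmuscingulate	IC_R	R	cingulate	paralimbic
rh_lateraloccipital	LOCC_R	R	occipital	association
rh_lateralorbitofrontal	LOF_R	R	frontal	paralimbic
rh_lingual	LING_R	R	occipital	association
rh_medialorbitofrontal	MOF_R	R	frontal	paralimbic
rh_middletemporal	MT_R	R	temporal	association
rh_paracentral	PARC_R	R	frontal	association
rh_parahippocampal	PARH_R	R	temporal	paralimbic
rh_parsopercularis	POPE_R	R	frontal	association
rh_parsorbitalis	PORB_R	R	frontal	association
rh_parstriangularis	PTRI_R	R	frontal	association
rh_pericalcarine	PERI_R	R	occipital	primary
rh_postcentral	PSTC_R	R	parietal	primary
rh_posteriorcingulate	PC_R	R	cingulate	paralimbic
rh_precentral	PREC_R	R	frontal	primary
rh_precuneus	PCUN_R	R	parietal	association
rh_rostralanteriorcingulate	RAC_R	R	cingulate	paralimbic
rh_rostralmiddlefrontal	RMF_R	R	frontal	association
rh_superiorfrontal	SF_R	R	frontal	association
rh_superiorparietal	SP_R	R	parietal	association
rh_superiortemporal	ST_R	R	temporal	association
rh_supramarginal	SMAR_R	R	parietal	association
rh_temporalpole	TP_R	R	temporal	association
rh_transversetemporal	TT_R	R	temporal	primary
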