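region	lobe	class	pct_subjects	avg_bc
PC_L	cingulate	paralimbic	45	32.9
ENT_L	temporal	association	40	39.1
LOF_L	frontal	paralimbic	40	39.1
TP_L	temporal	association	40	28.9
LOCC_R	occipital	association	40	37.4
LOCC_L	occipital	association	35	35.4
TT_L	temporal	primary	35	31.3
TT_R	temporal	primary	35	32.5
PARC_L	frontal	association	30	26
ENT_R	temporal	association	30	33.4
ST_R	temporal	association	30	36.3
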