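region	lobe	class	pct_subjects	avg_bc
LOCC_R	occipital	association	45	36
MOF_R	frontal	paralimbic	45	37.5
LOCC_L	occipital	association	40	44.7
LOF_L	frontal	paralimbic	40	39.1
PTRI_R	frontal	association	35	38.6
FUSI_L	temporal	association	30	31.1
IT_L	temporal	association	30	24.8
ST_L	temporal	association	30	35.3
LOF_R	frontal	paralimbic	30	32.4
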