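name	x	y	z
lh_bankssts	-41.4	-35.2	-11.9
lh_caudalanteriorcingulate	-41.4	-25.2	33.1
lh_caudalmiddlefrontal	-41.4	24.8	48.1
lh_cuneus	-41.4	-95.2	13.1
lh_entorhinal	-40.0	-33.3	-9.4
lh_frontalpole	-40.0	26.7	50.6
lh_fusiform	-37.7	-30.3	-7.4
lh_inferiorparietal	-41.4	-60.2	53.1
lh_inferiortemporal	-34.9	-26.5	-5.9
lh_insula	-41.4	-10.2	8.1
lh_isthmuscingulate	-40.0	-23.3	35.6
lh_lateraloccipital	-40.0	-93.3	15.6
lh_lateralorbitofrontal	-37.7	29.7	52.6
lh_lingual	-37.7	-90.3	17.6
lh_medialorbitofrontal	-34.9	33.5	54.1
lh_middletemporal	-31.7	-22.2	-5.1
lh_paracentral	-31.7	37.8	54.9
lh_parahippocampal	-31.7	-17.8	-5.1
lh_parsopercularis	-31.7	42.2	54.9
lh_parsorbitalis	-34.9	46.5	54.1
lh_parstriangularis	-37.7	50.3	52.6
lh_pericalcarine	-34.9	-86.5	19.1
lh_postcentral	-40.0	-58.3	55.6
lh_posteriorcingulate	-37.7	-20.3	37.6
lh_precentral	-40.0	53.3	50.6
lh_precuneus	-37.7	-55.3	57.6
lh_rostralanteriorcingulate	-34.9	-16.5	39.1
lh_rostralmiddlefrontal	-41.4	55.2	48.1
lh_superiorfrontal	-42.0	56.0	45.3
lh_superiorparietal	-34.9	-51.5	59.1
lh_superiortemporal	-34.9	-13.5	-5.9
lh_supramarginal	-31.7	-47.2	59.9
lh_temporalpole	-37.7	-9.7	-7.4
lh_transversetemporal	-40.0	-6.7	-9.4
rh_bankssts	41.4	-35.2	-11.9
rh_caudalanteriorcingulate	41.4	-25.2	33.1
rh_caudalmiddlefrontal	41.4	24.8	48.1
rh_cuneus	41.4	-95.2	13.1
rh_entorhinal	40.0	-33.3	-9.4
rh_frontalpole	40.0	26.7	50.6
rh_fusiform	37.7	-30.3	-7.4
rh_inferiorparietal	41.4	-60.2	53.1
rh_inferiortemporal	34.9	-26.5	-5.9
rh_insula	41.4	-10.2	8.1
rh_isthmuscingulate	40.0	-23.3	35.6
rh_lateraloccipital	40.0	-93.3	15.6
rh_lateralorbitofrontal	37.7	29.7	52.6
rh_lingual	37.7	-90.3	17.6
rh_medialorbitofrontal	34.9	33.5	54.1
rh_middletemporal	31.7	-22.2	-5.1
rh_paracentral	31.7	37.8	54.9
rh_parahippocampal	31.7	-17.8	-5.1
rh_parsopercularis	31.7	42.2	54.9
rh_parsorbitalis	34.9	46.5	54.1
rh_parstriangularis	37.7	50.3	52.6
rh_pericalcarine	34.9	-86.5	19.1
rh_postcentral	40.0	-58.3	55.6
rh_posteriorcingulate	37.7	-20.3	37.6
rh_precentral	40.0	53.3	50.6
rh_precuneus	37.7	-55.3	57.6
rh_rostralanteriorcingulate	34.9	-16.5	39.1
rh_rostralmiddlefrontal	41.4	55.2	48.1
rh_superiorfrontal	42.0	56.0	45.3
rh_superiorparietal	34.9	-51.5	59.1
rh_superiortemporal	34.9	-13.5	-5.9
rh_supramarginal	31.7	-47.2	59.9
rh_temporalpole	37.7	-9.7	-7.4
rh_transversetemporal	40.0	-6.7	-9.4
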