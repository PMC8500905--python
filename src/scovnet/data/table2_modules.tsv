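region_id	control_module	patient_module
lh_superiorfrontal	IV	I
lh_rostralmiddlefrontal	IV	I
lh_caudalmiddlefrontal	IV	I
lh_parsopercularis	I	I
lh_parsorbitalis	IV	I
lh_parstriangularis	IV	I
lh_lateralorbitofrontal	IV	IV
lh_medialorbitofrontal	IV	IV
lh_frontalpole	III	IV
lh_precentral	II	IV
lh_paracentral	II	IV
lh_entorhinal	I	II
lh_parahippocampal	III	III
lh_insula	I	I
lh_temporalpole	I	IV
lh_fusiform	II	II
lh_superiortemporal	I	II
lh_middletemporal	III	II
lh_inferiortemporal	III	II
lh_transversetemporal	II	III
lh_bankssts	II	II
lh_postcentral	II	IV
lh_supramarginal	III	I
lh_superiorparietal	II	I
lh_inferiorparietal	II	I
lh_precuneus	II	I
lh_lingual	I	III
lh_pericalcarine	II	III
lh_cuneus	II	I
lh_lateraloccipital	II	II
lh_rostralanteriorcingulate	III	II
lh_caudalanteriorcingulate	IV	II
lh_posteriorcingulate	IV	III
lh_isthmuscingulate	IV	III
rh_superiorfrontal	IV	IV
rh_rostralmiddlefrontal	II	I
rh_caudalmiddlefrontal	I	I
rh_parsopercularis	I	I
rh_parsorbitalis	IV	I
rh_parstriangularis	IV	I
rh_lateralorbitofrontal	IV	IV
rh_medialorbitofrontal	IV	IV
rh_frontalpole	III	IV
rh_precentral	I	IV
rh_paracentral	I	IV
rh_entorhinal	I	II
rh_parahippocampal	III	III
rh_insula	IV	I
rh_temporalpole	I	II
rh_fusiform	I	II
rh_superiortemporal	I	I
rh_middletemporal	III	II
rh_inferiortemporal	III	II
rh_transversetemporal	II	III
rh_bankssts	I	I
rh_postcentral	I	I
rh_supramarginal	I	I
rh_superiorparietal	II	II
rh_inferiorparietal	II	II
rh_precuneus	II	II
rh_lingual	III	III
rh_pericalcarine	II	IV
rh_cuneus	II	III
rh_lateraloccipital	I	III
rh_rostralanteriorcingulate	IV	III
rh_caudalanteriorcingulate	IV	II
rh_posteriorcingulate	IV	III
rh_isthmuscingulate	IV	III
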