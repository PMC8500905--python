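region_id	hemisphere	dk_name	lobe	display_name
lh_superiorfrontal	lh	superiorfrontal	frontal	Left Superior frontal
lh_rostralmiddlefrontal	lh	rostralmiddlefrontal	frontal	Left Rostral middle frontal
lh_caudalmiddlefrontal	lh	caudalmiddlefrontal	frontal	Left Caudal middle frontal
lh_parsopercularis	lh	parsopercularis	frontal	Left Inferior frontal (pars opercularis)
lh_parsorbitalis	lh	parsorbitalis	frontal	Left Inferior frontal (pars orbitalis)
lh_parstriangularis	lh	parstriangularis	frontal	Left Inferior frontal (pars triangularis)
lh_lateralorbitofrontal	lh	lateralorbitofrontal	frontal	Left Lateral orbitofrontal
lh_medialorbitofrontal	lh	medialorbitofrontal	frontal	Left Medial orbitofrontal
lh_frontalpole	lh	frontalpole	frontal	Left Frontal pole
lh_precentral	lh	precentral	frontal	Left Precentral
lh_paracentral	lh	paracentral	frontal	Left Paracentral
lh_entorhinal	lh	entorhinal	temporal	Left Entorhinal
lh_parahippocampal	lh	parahippocampal	temporal	Left Parahippocampal
lh_insula	lh	insula	temporal	Left Insula
lh_temporalpole	lh	temporalpole	temporal	Left Temporal pole
lh_fusiform	lh	fusiform	temporal	Left Fusiform
lh_superiortemporal	lh	superiortemporal	temporal	Left Superior temporal
lh_middletemporal	lh	middletemporal	temporal	Left Middle temporal
lh_inferiortemporal	lh	inferiortemporal	temporal	Left Inferior temporal
lh_transversetemporal	lh	transversetemporal	temporal	Left Transverse temporal
lh_bankssts	lh	bankssts	temporal	Left Banks of superior temporal sulcus
lh_postcentral	lh	postcentral	parietal	Left Postcentral
lh_supramarginal	lh	supramarginal	parietal	Left Supramarginal
lh_superiorparietal	lh	superiorparietal	parietal	Left Superior parietal
lh_inferiorparietal	lh	inferiorparietal	parietal	Left Inferior parietal
lh_precuneus	lh	precuneus	parietal	Left Precuneus
lh_lingual	lh	lingual	occipital	Left Lingual
lh_pericalcarine	lh	pericalcarine	occipital	Left Pericalcarine
lh_cuneus	lh	cuneus	occipital	Left Cuneus
lh_lateraloccipital	lh	lateraloccipital	occipital	Left Lateral occipital
lh_rostralanteriorcingulate	lh	rostralanteriorcingulate	cingulate	Left Rostral anterior cingulate
lh_caudalanteriorcingulate	lh	caudalanteriorcingulate	cingulate	Left Caudal anterior cingulate
lh_posteriorcingulate	lh	posteriorcingulate	cingulate	Left Posterior cingulate
lh_isthmuscingulate	lh	isthmuscingulate	cingulate	Left Isthmus cingulate
rh_superiorfrontal	rh	superiorfrontal	frontal	Right Superior frontal
rh_rostralmiddlefrontal	rh	rostralmiddlefrontal	frontal	Right Rostral middle frontal
rh_caudalmiddlefrontal	rh	caudalmiddlefrontal	frontal	Right Caudal middle frontal
rh_parsopercularis	rh	parsopercularis	frontal	Right Inferior frontal (pars opercularis)
rh_parsorbitalis	rh	parsorbitalis	frontal	Right Inferior frontal (pars orbitalis)
rh_parstriangularis	rh	parstriangularis	frontal	Right Inferior frontal (pars triangularis)
rh_lateralorbitofrontal	rh	lateralorbitofrontal	frontal	Right Lateral orbitofrontal
rh_medialorbitofrontal	rh	medialorbitofrontal	frontal	Right Medial orbitofrontal
rh_frontalpole	rh	frontalpole	frontal	Right Frontal pole
rh_precentral	rh	precentral	frontal	Right Precentral
rh_paracentral	rh	paracentral	frontal	Right Paracentral
rh_entorhinal	rh	entorhinal	temporal	Right Entorhinal
rh_parahippocampal	rh	parahippocampal	temporal	Right Parahippocampal
rh_insula	rh	insula	temporal	Right Insula
rh_temporalpole	rh	temporalpole	temporal	Right Temporal pole
rh_fusiform	rh	fusiform	temporal	Right Fusiform
rh_superiortemporal	rh	superiortemporal	temporal	Right Superior temporal
rh_middletemporal	rh	middletemporal	temporal	Right Middle temporal
rh_inferiortemporal	rh	inferiortemporal	temporal	Right Inferior temporal
rh_transversetemporal	rh	transversetemporal	temporal	Right Transverse temporal
rh_bankssts	rh	bankssts	temporal	Right Banks of superior temporal sulcus
rh_postcentral	rh	postcentral	parietal	Right Postcentral
rh_supramarginal	rh	supramarginal	parietal	Right Supramarginal
rh_superiorparietal	rh	superiorparietal	parietal	Right Superior parietal
rh_inferiorparietal	rh	inferiorparietal	parietal	Right Inferior parietal
rh_precuneus	rh	precuneus	parietal	Right Precuneus
rh_lingual	rh	lingual	occipital	Right Lingual
rh_pericalcarine	rh	pericalcarine	occipital	Right Pericalcarine
rh_cuneus	rh	cuneus	occipital	Right Cuneus
rh_lateraloccipital	rh	lateraloccipital	occipital	Right Lateral occipital
rh_rostralanteriorcingulate	rh	rostralanteriorcingulate	cingulate	Right Rostral anterior cingulate
rh_caudalanteriorcingulate	rh	caudalanteriorcingulate	cingulate	Right Caudal anterior cingulate
rh_posteriorcingulate	rh	posteriorcingulate	cingulate	Right Posterior cingulate
rh_isthmuscingulate	rh	isthmuscingulate	cingulate	Right Isthmus cingulate
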