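subject_id	vhl_hgvs_c	vhl_classification	zygosity	deleted_exons	differential_findings	evaluated_in_genetics	age_years	sex	personal_tumors	personal_features	non_vhl_tumors	family_history_vhl	family_degree	somatic_tested	somatic_alterations
patient-21	c.208G>A	P	heterozygous		none	true	16	female				positive	first	false
patient-22	c.345C>A	VUS	heterozygous		none	true	47	female	cns_hemangioblastoma			negative		false
patient-23	c.532C>G	VUS	heterozygous		none	true	58	male	paraganglioma			negative		false
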