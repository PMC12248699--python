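subject_id	vhl_hgvs_c	vhl_classification	zygosity	deleted_exons	differential_findings	evaluated_in_genetics	age_years	sex	personal_tumors	personal_features	non_vhl_tumors	family_history_vhl	family_degree	somatic_tested	somatic_alterations
portal-01	c.340+578C>T	VUS	heterozygous		none	true	44	female				negative		false
portal-02	c.340+578C>T	VUS	heterozygous		none	true	52	female				negative		false
portal-03	c.340+578C>T	VUS	heterozygous		none	true	61	male				negative		false
portal-04	c.340+578C>T	VUS	heterozygous		none	true	68	female				negative		false
portal-05	c.340+578C>T	VUS	heterozygous		none	true	57	female			breast carcinoma	negative		false
portal-06	c.340+578C>T	VUS	heterozygous		none	true	63	male			colon adenocarcinoma	negative		false
portal-07	c.340+578C>T	VUS	heterozygous		none	true	71	female			melanoma	negative		false
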