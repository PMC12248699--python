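subject_id	vhl_hgvs_c	vhl_classification	zygosity	deleted_exons	differential_findings	evaluated_in_genetics	age_years	sex	personal_tumors	personal_features	non_vhl_tumors	family_history_vhl	family_degree	somatic_tested	somatic_alterations
ecyt2-01	c.598C>T	P_ECYT2	heterozygous		none	true	39	female				negative		false
ecyt2-02	c.598C>T	P_ECYT2	heterozygous		none	true	55	male				negative		false
ecyt2-03	c.562C>G	P_ECYT2	heterozygous		none	true	48	female			urothelial carcinoma	negative		false
ecyt2-04	c.388G>A	P_ECYT2	heterozygous		none	true	62	female				negative		false
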