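subject_id	vhl_hgvs_c	vhl_classification	zygosity	deleted_exons	differential_findings	evaluated_in_genetics	age_years	sex	personal_tumors	personal_features	non_vhl_tumors	family_history_vhl	family_degree	somatic_tested	somatic_alterations
demo-01		P	heterozygous	1,2,3	none	true	28	female	cns_hemangioblastoma;retinal_hemangioblastoma			negative		false
demo-02	c.341-1G>A	P	heterozygous		none	true	36	female	cns_hemangioblastoma;rcc			negative		true	c.263G>A|snv|41||230|70|0|4|rcc
demo-03	c.464-1G>C	LP	heterozygous		none	true	33	male	rcc:2;pheochromocytoma			positive	first	false
demo-04	c.292T>C	P	heterozygous		none	true	81	female			cervical carcinoma	negative		false
demo-05	c.340+705G>A	VUS	heterozygous		none	true	59	female				negative		false
demo-06	c.613C>T	VUS	heterozygous		none	true	66	male	rcc			negative		true	c.499C>T|snv|74||180|62|0|2|rcc;|one_copy_deletion||-0.9|||||rcc
demo-07	c.545G>A	VUS	heterozygous		SDHB:P	true	42	female	paraganglioma:1:sdh_deficient			negative		false
demo-08	c.208G>A	P	compound_heterozygous		none	true	24	female				negative		false
demo-09	c.345C>A	VUS	heterozygous		none	true	19	female	retinal_hemangioblastoma			negative		false
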