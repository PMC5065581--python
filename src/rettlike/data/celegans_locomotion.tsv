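human_gene	ortholog	similarity_pct	identity_pct	mutation	locomotion_phenotype
GABBR2	gbb-2	53	34	deletion	normal
MGRN1	C11H1.3	58	41	deletion	locomotion defective
CHRNA5	unc-63	58	40	deletion	locomotion defective
ZNF620	pag-3	65	47	deletion	locomotion defective
ANKRD31	unc-44	59	39	deletion	locomotion defective
PDLIM7	alp-1	65	47	deletion	locomotion defective
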