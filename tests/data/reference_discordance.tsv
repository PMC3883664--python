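patient_id	pct_unamp_unique_lowcov_in_wga	pct_wga_unique_lowcov_in_unamp	pct_wga_unique_rna_lowcov	n_tumor_specific	pct_confirmed_in_unamplified	pct_tumor_specific_rna_lowcov
118	71.7	57.6	69.9	1080	70.4	68.9
140	72.7	57.7	65.0	1644	77.9	64.2
210	84.8	21.8	62.5	630	33.3	59.4
247	90.9	5.7		2095	13.8	
255	81.6	43.1	65.0	698	62.9	63.0
295	79.7	43.7	100.0	3510	81.5	100.0
278	73.3	50.9	63.4	1819	82.1	58.6
322	79.8	9.4		5377	11.4	
396	79.7	53.6	64.9	1778	39.0	63.9
412	72.3	32.4	58.9	2580	60	60.5
421	78.3	27.2	100.0	994	38.1	100.0
541	82.0	25.9		1098	32.2	
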