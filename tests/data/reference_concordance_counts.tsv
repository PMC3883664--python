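patient_id	n_wga_only	n_shared	n_unamp_only	pct_wga_only_printed	pct_shared_printed	pct_unamp_only_printed
118	722	10985	3260	6	73	23
140	759	11781	1953	6	81	14
210	1099	11413	2715	9	75	19
247	1964	9483	4591	17	59	33
255	606	11162	2615	5	78	19
278	861	12250	1535	7	84	11
295	650	11464	2716	5	77	19
322	3866	10821	3023	26	61	22
396	2076	10151	2119	17	71	17
412	1559	12216	1374	11	81	10
421	1204	12108	2133	9	78	15
541	1398	13350	3096	9	75	19
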