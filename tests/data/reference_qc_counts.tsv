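assay	sample_id	n_het	n_hom	het_hom_printed	ts_tv_printed	coverage_printed
wga_tumor	118	7359	4136	1.78	3.42	39.67
wga_tumor	127	8068	4627	1.74	3.32	72.28
wga_tumor	140	7904	4411	1.79	3.25	59.33
wga_tumor	146	8104	4247	1.91	3.23	61.05
wga_tumor	210	7806	4333	1.80	2.96	53.72
wga_tumor	225	8088	4258	1.90	2.91	83.70
wga_tumor	247	7091	3498	2.03	2.58	24.65
wga_tumor	255	7387	4215	1.75	3.29	62.69
wga_tumor	278	8328	4612	1.81	3.11	107.10
wga_tumor	295	7517	4451	1.69	3.24	48.06
wga_tumor	322	9019	4173	2.16	2.53	49.57
wga_tumor	344	8107	4300	1.89	3.08	59.31
wga_tumor	396	7408	4169	1.78	3.06	31.25
wga_tumor	412	8755	4752	1.84	2.84	98.08
wga_tumor	421	8552	4489	1.91	2.95	81.62
wga_tumor	541	9669	4511	2.14	3.11	35.20
unamplified_tumor	118	9006	4823	1.87	2.95	48.39
unamplified_tumor	127	14029	3152	4.45	3.27	87.78
unamplified_tumor	140	8725	4875	1.79	3.16	64.98
unamplified_tumor	146	15193	3123	4.86	3.18	85.07
unamplified_tumor	210	8860	5117	1.73	3.17	79.28
unamplified_tumor	225	14270	3081	4.63	3.30	73.46
unamplified_tumor	247	8879	5066	1.75	3.22	108.08
unamplified_tumor	255	8743	4891	1.79	3.26	81.93
unamplified_tumor	295	8717	5067	1.72	3.03	54.27
unamplified_tumor	278	8656	4998	1.73	3.21	88.89
unamplified_tumor	322	8650	4991	1.73	3.11	73.08
unamplified_tumor	344	14161	3006	4.71	3.15	77.05
unamplified_tumor	396	7627	4455	1.71	3.27	36.48
unamplified_tumor	412	8473	4940	1.72	3.21	73.48
unamplified_tumor	421	9085	4977	1.83	3.14	81.82
unamplified_tumor	541	10900	5329	2.05	3.17	73.85
wga_normal	118	7476	4154	1.80	3.43	73.07
wga_normal	127	9290	4619	2.01	2.64	101.20
wga_normal	140	7288	3984	1.83	3.41	59.76
wga_normal	146	8292	4613	1.80	3.32	67.14
wga_normal	210	7894	4334	1.82	3.13	48.37
wga_normal	225	11154	4935	2.26	2.07	127.39
wga_normal	247	8925	4940	1.81	3.27	123.26
wga_normal	255	8560	4771	1.79	3.25	83.78
wga_normal	295	6506	3414	1.91	3.18	27.59
wga_normal	278	6961	3966	1.76	3.10	30.67
wga_normal	322	7747	4610	1.68	3.29	56.95
wga_normal	344	8082	4298	1.88	3.09	60.13
wga_normal	396	7276	4035	1.80	3.18	27.70
wga_normal	412	8010	4156	1.93	2.84	38.52
wga_normal	421	8561	4579	1.87	3.11	64.07
wga_normal	541	10411	4840	2.15	3.03	78.53
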