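# colonsim fixture schema v1: colon-administration study arms with observed and vendor-software-predicted outcomes
# auc in ug*h/mL; frel = AUC_colon/AUC_ref; fabs_colon_pred in percent of dose
drug	dose_mg	formulation	route	auc_obs	auc_pred_gisim	auc_pred_gastroplus	frel_obs	frel_pred_gisim	frel_pred_gastroplus	fabs_colon_pred_gisim_pct	fabs_colon_pred_gastroplus_pct
Aprepitant	24	nanosuspension	colon	1.01	0.24	21.5	0.04	0.02	1.00	1.6	100.0
Atenolol	5	solution	colon	0.06	0.04	0.00	0.27	0.21	0.01	23.1	3.0
AZ1	30	solution	colon	0.94	1.10	0.98	0.46	0.80	0.71	79.6	71.7
AZ1	40	suspension	colon	0.22	0.23	0.53	0.20	0.35	0.41	13.6	30.2
AZ2	15	solution	colon	2.76	3.52	4.21	0.61	0.78	0.94	78.6	94.6
AZ2	20	suspension	colon	4.76	4.68	5.23	1.05	1.05	1.17	78.4	88.4
AZ3	75	solution	colon	0.46	1.83	1.53	0.23	0.91	0.73	86.6	72.9
AZ3	75	suspension	colon	0.38	0.18	0.50	0.19	0.09	0.24	9.1	25.9
Cimetidine	87	solution	colon	3.55	1.00	1.09	0.68	0.52	0.50	46.2	50.2
Enalaprilat	20	solution	colon	0.12	0.24	0.05	0.43	0.23	0.05	25.6	10.2
Felodipine	10	solution	colon	0.03	0.17	0.37	0.39	0.93	0.86	87.8	86.1
Felodipine	10	suspension	colon	0.02	0.02	0.13	0.27	0.09	0.30	9.1	30.1
Ketoprofen	2.5	solution	colon	0.29	0.32	0.36	0.82	0.83	0.96	89.6	99.2
Metoprolol	12.5	solution	colon	0.04	0.05	0.03	0.75	0.60	0.52	73.7	70.4
Nifedipine	24	solution	colon	0.16	0.12	0.07	0.93	0.78	0.49	77.1	50.3
Nifedipine	12	suspension	colon	0.04	0.03	0.02	0.35	0.73	0.30	22.7	17.2
Propranolol	48	solution	colon	4.51	1.27	1.15	0.98	0.67	0.58	70.7	64.1
Ranitidine	63	solution	colon	1.33	0.81	0.05	0.42	0.46	0.02	38.9	2.7
Theophylline	120	solution	colon	104	98.8	66.7	0.81	0.86	0.59	87.1	62.8
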