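# colonsim fixture schema v1: systemic compartmental PK parameters (per-kg) and first-pass extraction
drug	cl_l_h_kg	v_l_kg	k12_1_h	k21_1_h	k13_1_h	k31_1_h	fu	first_pass_pct
Aprepitant	0.09	0.204	6.887	2.722			0.014	2.74
Atenolol	0.268	0.97	1.29	0.584			0.9	3.45
AZ1	0.467	0.116	27.82	6.96	4.839	1.039	0.063	35.35
AZ2	0.086	0.366	0.073	0.011			n/a	2.59
AZ3	0.624	0.364	7.153	2.369			0.0022	47.25
Cimetidine	0.714	0.424	5.909	3.472	0.218	0.323	0.9	21.12
Enalaprilat	0.155	0.751	1.149	0.338			n/a	0.47
Felodipine	1.142	0.65					0.001	40.53
Ketoprofen	0.146	0.158	2.018	1.76	0.394	0.188	n/a	11.03
Metoprolol	2.643	8.92					0.85	53.0
Nifedipine	2.638	1.368	2.709	0.69			0.076	79.95
Propranolol	0.934	1.087	5.828	2.782	1.887	0.09	0.19	62.0
Ranitidine	0.60	0.13	7.942	1.215	0.289	0.141	0.71	13.69
Theophylline	0.083	0.558					0.85	2.51
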