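# colonsim fixture schema v1: biopharmaceutics and physicochemical drug properties
# pka: semicolon-separated value+kind tokens, kind a=acid b=base; "neutral"/empty = none
# s_buffer_ph: reference pH of the buffer solubility; "intrinsic" = intrinsic solubility, "water" = unbuffered water
# s_fassif empty = no biorelevant solubility measured (buffer value applies, no micellar enhancement)
drug	mw_g_mol	pka	logd74	density_g_ml	particle_radius_um	diffusion_1e9_m2_s	peff_dog_1e4_cm_s	s_buffer_ug_ml	s_buffer_ph	s_fassif_ug_ml	bcs
Aprepitant	534	9.15a;2.4b	6.9	1.51	0.12	0.63	7.1	0.37	6.5	23	II
Atenolol	266	9.21b	-2	1.1		0.72	0.82	13300	intrinsic		III
AZ1	450	12a;2.2b	2.9	1.38	25	0.68	4.16	8.9	6.5	17	II
AZ2	400	11a	1.36	1.38	5	0.68	3.92	253	6.5	253	IV
AZ3	520	3.05b	3.89	1.24	5	0.60	6.9	7	7.4	360	IV
Cimetidine	252	6.76b	0.23	1.15		0.77	1.03	24000	6.8		III
Enalaprilat	348	7.84a;3.17b	-1			0.69	0.82	5000	water		III
Felodipine	384	neutral	4.3	1.28		0.67	7.7	1	6.5	53	II
Ketoprofen	254	4.02a	0.1	1.14		0.75	8.7	51	1.2		II
Metoprolol	267	9.18b	0	1.07		0.71	4.83	43000	6.5		I
Nifedipine	346	neutral	2.07				3.6	11	6.5	17	II
Propranolol	259	9.4b	1.16			0.72	2.91	1000	6.5		I
Ranitidine	351	7.62b;2.22b	-0.94	1.15		0.69	0.80	1750	7.4		III
Theophylline	180	8.4a	-0.14	1.25		0.85	7.2	1800	7.4		I
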