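digester	ts_percent	vs_percent	hrt_days	temperature_c	total_n_g_per_l	ph	vfa_g_per_l	olr_gvs_per_l_day	tan_g_per_l	ammonia_g_per_l	substrate
CD01	5.7	3.5	45	38	8.7	7.8	1.3	3.0	4.6	0.365	SSMOW, slaughterhouse waste
CD02	4.8	3.8	55	38	9.1	7.8	0.8	2.9	5.1	0.408	Thin stillage
CD03	2.6	2.0	30	37	2.6	7.3	<0.1	3.0	0.9	0.022	SSMOW
CD04	7.1	1.3	70	38	6.2	7.7	3.0	3.0	3.5	0.218	Grass, wheat-based stillage
WWTP01	2.7	1.9	17	38	2.5	7.3	<0.1	2.4	1.4	0.036	Mixed sludge
WWTP02	3.5	2.5	23	37	2.9	7.5	0.2	3.1	1.6	0.063	Mixed sludge
WWTP03	2.4	1.9	18	38	1.8	7.3	0.1	2.0	0.9	0.022	Mixed sludge
WWTP04	3.4	2.4	30	37	2.9	7.5	0.3	1.6	1.5	0.058	Mixed sludge
WWTP05	2.5	2.1	22	37	2.1	7.3	0.1	2.8	1.1	0.027	Mixed sludge
WWTP06	2.1	5.5	26	34	1.8	7.3	<0.1	1.1	1.1	0.023	Mixed sludge
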