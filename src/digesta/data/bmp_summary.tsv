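inoculum	substrate	days_to_100pct	days_to_80pct	days_to_50pct	final_potential_nml_per_gvs	final_potential_sd
CD01	cellulose	41	24	18	319	24
CD01	straw	110	56	28	258	47
CD02	cellulose	110	71	47	307	54
CD02	straw	75	62	45	233	38
CD03	cellulose	12	6	5	347	15
CD03	straw	60	23	8	316	37
CD04	cellulose	20	10	8	348	24
CD04	straw	26	10	8	274	17
WWTP01	cellulose	57	15	7	350	7
WWTP01	straw	110	44	19	290	9
WWTP02	cellulose	36	13	7	314	34
WWTP02	straw	57	24	14	240	38
WWTP03	cellulose	27	11	6	322	7
WWTP03	straw	75	25	13	310	76
WWTP04	cellulose	29	15	8	325	8
WWTP04	straw	60	20	11	277	11
WWTP05	cellulose	45	9	6	376	8
WWTP05	straw	59	30	10	281	32
WWTP06	cellulose	49	13	8	324	13
WWTP06	straw	135	39	18	296	8
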