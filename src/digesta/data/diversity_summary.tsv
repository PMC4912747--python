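sample	chao1	s_obs	shannon_bits	simpson
CD01	58	52	1.937	0.456
CD02	94	69	3.111	0.763
CD03	147	120	5.042	0.947
CD04	109	96	3.619	0.767
WWTP01	294	227	5.851	0.956
WWTP02	215	187	4.737	0.861
WWTP03	304	258	5.823	0.930
WWTP04	209	135	3.088	0.609
WWTP05	354	244	5.899	0.955
WWTP06	280	242	5.857	0.930
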