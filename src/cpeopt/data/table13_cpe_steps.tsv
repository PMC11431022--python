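row	TPC	TPC_sd	TC	TC_sd	AA	AA_sd
Step 1	416.72	4.33	4.57	0.23	998.64	2.09
Step 2	136.06	1.19	0	0	362.82	4.63
Sum	552.78	5.52	4.57	0.23	1361.46	6.72
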