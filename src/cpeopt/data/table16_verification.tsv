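sample	X1	X2	X3	X4	X5	X6	X7	X8	X9	X10	X11	model_TP	model_TC	model_AA	exp_TP	exp_TC	exp_AA
3	Triton X-100	2	1:10	1.5	35	60	NaCl	16	2473	10	Step 2	107.48	8.01	468.75	105.42	8.37	459.51
6	Triton X-100	2	1:10	1.5	55	60	KCl	18	9892	20	Step 1	139.12	7.00	465.77	144.23	7.02	465.22
9	Tween 80	10	1:50	1.5	35	60	KCl	16	9892	10	Step 2	346.43	1.81	812.89	356.28	1.82	807.12
10	Tween 80	10	1:50	1.5	35	20	NaCl	16	2473	20	Step 1	165.95	5.11	483.30	165.49	5.37	495.19
optimal	Tween 80	2	1:100	6.61	35	60	NaCl	16	7906	13.36	Step 1	352.49	16.59	989.02	341.55	16.02	983.02
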