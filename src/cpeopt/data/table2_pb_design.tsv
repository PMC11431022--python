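run	X1	X2	X3	X4	X5	X6	X7	X8	X9	X10	X11	TPC	TC	AA
1	Tween 80	10	1:10	7.5	75	60	NaCl	18	9892	20	Step 2	0	0	0
2	Triton X-100	10	1:100	7.5	75	60	KCl	16	2473	20	Step 1	0	12.58	164.88
3	Triton X-100	2	1:10	1.5	75	60	NaCl	16	2473	10	Step 2	105.61	7.89	493.27
4	Tween 80	2	1:100	7.5	35	60	NaCl	18	2473	10	Step 1	348.56	16.4	968.99
5	Triton X-100	10	1:100	1.5	75	20	NaCl	18	9892	10	Step 1	0	0	0
6	Triton X-100	2	1:10	1.5	35	60	KCl	18	9892	20	Step 1	142.11	6.81	487.2
7	Triton X-100	2	1:100	7.5	35	20	NaCl	16	9892	20	Step 2	0	8.57	0
8	Tween 80	2	1:100	1.5	75	20	KCl	18	2473	20	Step 2	0	0	0
9	Tween 80	10	1:100	1.5	35	60	KCl	16	9892	10	Step 2	335.48	1.86	825.93
10	Tween 80	10	1:10	1.5	35	20	NaCl	16	2473	20	Step 1	172.22	5.05	471.32
11	Triton X-100	10	1:10	7.5	35	20	KCl	18	2473	10	Step 2	0	0	0
12	Tween 80	2	1:10	7.5	75	20	KCl	16	9892	10	Step 1	109.33	8.61	407.35
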