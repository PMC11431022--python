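compound	class	CPE	water	ultrasound	ultrasound_CPE	microwave	microwave_CPE
p-Hydroxybenzoic acid	phenol	0.41	0.67	0.88	0.71	1.40	0
Gallic acid	phenol	3.75	9.64	14.23	3.72	7.62	3.57
Protocatechin	phenol	2.90	3.32	2.75	2.94	3.39	3.49
Caffeic acid	phenol	0.55	0.38	0.34	0.46	0.41	0.69
Catechin	phenol	42.86	29.07	3.27	15.58	8.37	13.02
Syringic acid	phenol	2.61	1.75	1.55	2.13	1.82	2.49
Vanillic acid	phenol	5.79	5.14	3.96	6.00	5.18	6.60
Total phenols	phenol_total	58.87	49.96	26.98	31.54	28.19	29.87
beta-cryptoxanthin	carotenoid	1.91	0	1.27	1.77	0	1.37
Lutein	carotenoid	0.04	0	0.01	0.03	0	0.04
Zeaxanthin	carotenoid	0.03	0	0.01	0.01	0	0.02
beta-carotene	carotenoid	0.02	0	0	0.01	0	0.01
Total carotenoids	carotenoid_total	2.00	0	1.29	1.82	0	1.44
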