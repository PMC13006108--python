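sequence	variant	site	predicted_gu	predicted_min	experimental_min	experimental_gu	shift_min	shift_gu
ALPAPIEKTISK	unmodified	-	5.74	17.15
ALPAPIEKTISK	glycated	K8	6.09	17.75	18.41	6.48	1.26	0.74
LTVDKSR	unmodified	-	5.87	17.37	18.85	6.74
LTVDKSR	glycated	K5	6.22	17.97	19.52	7.15	1.15	0.27
EVQLVESGGGLVQPGR	unmodified	-	5.09	15.95	16.68	5.48
EVQLVESGGGLVQPGR	glycated	protein-N-term	5.44	16.61	17.47	5.93	1.52	0.64
VVSVLTVLHQDWLNGKEYK	unmodified	-	5.91	17.44
VVSVLTVLHQDWLNGKEYK	glycated	K16	6.26	18.04	17.64	6.02	0.20	0.11
VSNKALPAPIEK	unmodified	-	6.31	18.13
VSNKALPAPIEK	glycated	K4	6.66	18.71	20.31	7.64	1.18	0.83
DELTKNQVSLTCLVK	unmodified	-	6.94	19.17
DELTKNQVSLTCLVK	glycated	K5	7.29	19.74	19.67	7.24	0.50	0.30
APKLLIYAASTLQSGVPSR	unmodified	-	4.78	15.33	16.63	5.45
APKLLIYAASTLQSGVPSR	glycated	K3	5.13	16.02	16.42	5.38	1.09	0.60
APYTFGQGTKVEIK	unmodified	-	6.35	18.20	18.51	6.54
APYTFGQGTKVEIK	glycated	K10	6.70	18.77	18.92	6.79	0.72	0.43
VYACEVTHQGLSSPVTKSFNR	unmodified	-	7.50	20.08	20.21	7.58
VYACEVTHQGLSSPVTKSFNR	glycated	K17	7.85	20.74	20.62	7.84	0.54	0.34
DIQMTQSPSSLSASVGDR	unmodified	-	6.83	18.99
DIQMTQSPSSLSASVGDR	glycated	protein-N-term	7.18	19.57	20.22	7.58	1.23	0.75
ADYEKHK	unmodified	-	8.59	21.73
ADYEKHK	glycated	K5	8.94	22.16	22.44	9.12	0.71	0.53
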