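sequence	variant	site	predicted_gu	predicted_min	experimental_min	experimental_gu	shift_min	shift_gu
VSCKASGFNIK	unmodified	-	5.86	17.40	16.19	5.16
VSCKASGFNIK	glycated	K4	6.21	17.93	17.67	6.03	0.27	0.17
ASGFNIKDTYIHWVR	unmodified	-	5.47	16.75	17.89	6.18
ASGFNIKDTYIHWVR	glycated	K7	5.82	17.33	17.99	6.25	1.24	0.78
VSNKGLPSSIEK	unmodified	-	6.75	18.67	19.74	7.82
VSNKGLPSSIEK	glycated	K4	7.10	19.08	20.01	8.40	1.34	0.86
GLPSSIEKTISK	unmodified	-	6.15	17.85	18.46	6.59
GLPSSIEKTISK	glycated	K8	6.50	18.34	19.07	7.09	1.22	0.94
EPQVYTLPPSQEEMTKNQVSLTCLVK	unmodified	-	8.99	19.92
EPQVYTLPPSQEEMTKNQVSLTCLVK	glycated	K16	9.34	19.62	20.32	9.59	0.40	0.60
LTVDKSR	unmodified	-	5.79	17.29
LTVDKSR	glycated	K5	6.14	17.83	18.16	6.37	0.87	0.58
DIQMTQSPSSLSASVGDR	unmodified	-	6.83	18.77
DIQMTQSPSSLSASVGDR	glycated	protein-N-term	7.18	19.17	19.59	7.34	0.82	0.51
TSQDINKYMAWYQQTPGK	unmodified	-	7.92	19.81
TSQDINKYMAWYQQTPGK	glycated	K7	8.27	19.96	20.16	8.30	0.35	0.38
YMAWYQQTPGKAPR	unmodified	-	5.69	17.13	17.22	5.75
YMAWYQQTPGKAPR	glycated	K11	6.04	17.68	17.79	6.11	0.66	0.42
TVAAPSVFIFPPSDEQLKSGTASVVCLLNNFYPR	unmodified	-	4.92	14.78	15.46	4.78
TVAAPSVFIFPPSDEQLKSGTASVVCLLNNFYPR	glycated	K18	5.27	16.44	15.57	4.84	0.79	0.16
EAKVQWK	unmodified	-	5.92	17.50
EAKVQWK	glycated	K3	6.27	18.02	18.70	6.77	1.20	0.85
VYACEVTHQGLSSPVTKSFNR	unmodified	-	8.48	20.02
VYACEVTHQGLSSPVTKSFNR	glycated	K17	8.83	19.99	20.26	8.58	0.24	0.10
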