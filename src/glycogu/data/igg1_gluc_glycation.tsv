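sequence	variant	site	predicted_gu	predicted_min	experimental_min	experimental_gu
IKRTVAAPSVFIFPPSDE	unmodified	-			14.06	4.20
IKRTVAAPSVFIFPPSDE	glycated	K2	4.72	15.21	15.30	4.76
VKFNWYVDGVE	unmodified	-			12.14	3.43
VKFNWYVDGVE	glycated	K2	3.95	13.48	13.74	4.06
KSRWQQGNVFSCSVMHE	unmodified	-			21.79	8.64
KSRWQQGNVFSCSVMHE	glycated	K1	9.16	22.38	22.52	9.32
ALHNHYTQKSLSLSPG	unmodified	-			19.89	7.38
ALHNHYTQKSLSLSPG	glycated	K9	7.90	20.72	20.97	7.89
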