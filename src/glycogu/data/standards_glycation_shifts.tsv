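analyte	sequence	site	shift_min	shift_gu
cytochrome_c_bovine	TGQAPGFSYTDANKNK	K14	0.22	0.14
cytochrome_c_bovine	HKTGPNLHGLFGR	K2	0.28	0.18
cytochrome_c_bovine	EDLIAYLKK	K8	0.31	0.19
cytochrome_c_bovine	KTGQAPGFSYTDANK	K1	0.59	0.31
cytochrome_c_bovine	KIFVQK	K1	0.71	0.40
cytochrome_c_bovine	MIFAGIKK	K7	0.72	0.41
cytochrome_c_bovine	GITWGEETLMEYLENPKK	K17	0.78	0.46
cytochrome_c_bovine	KYIPGTK	K1	0.79	0.46
cytochrome_c_bovine	YIPGTKMIFAGIK	K6	1.15	0.53
cytochrome_c_bovine	YIPGTKMIFAGIK	K6	1.04	0.51
cytochrome_c_bovine	MIFAGIKK	K7	0.45	0.24
insulin_bovine	GIVEQCCASVCSLYQLENYCN	protein-N-term	0.77	0.49
insulin_bovine	FVNQHLCGSHLVEALYLVCGERGFFYTPKA	protein-N-term	0.73	0.45
glufib	EGVNDNEEGFFSAR	protein-N-term	0.46	0.24
bradykinin	RPPGFSPFR	protein-N-term	0.68	0.35
leucine_enkephalin	YGGFL	protein-N-term	0.21	0.12
substance_p_frag_2_11	PKPQQFFGLM	K2	1.19	0.54
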