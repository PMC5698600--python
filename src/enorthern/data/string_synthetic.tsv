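protein1	protein2	neighborhood	fusion	cooccurrence	coexpression	experiments	database	textmining	combined_score
FASN	SCD5	0	0	0	0.62	0.15	0.60	0.82	0.95
FASN	ACSS2	0	0	0	0.45	0	0	0.70	0.82
FASN	SREBF1	0	0	0	0.41	0.30	0.50	0.90	0.96
FASN	ACACA	0	0	0	0.55	0	0.80	0.92	0.98
FASN	GPAM	0	0	0	0.33	0	0	0.66	0.73
FASN	FADS2	0	0	0	0.30	0	0	0.58	0.68
SREBF1	SCD5	0	0	0	0.20	0	0.55	0.80	0.90
SREBF1	INSIG1	0	0	0	0	0.65	0.70	0.88	0.96
SREBF1	GPAM	0	0	0	0	0	0	0.72	0.74
SREBF1	SCAP	0	0	0	0	0.78	0.85	0.92	0.98
SREBF1	SREBF2	0	0	0	0.18	0	0	0.85	0.88
SREBF2	SCAP	0	0	0	0	0.80	0.85	0.93	0.98
SREBF2	SCD5	0	0	0	0	0	0.50	0.72	0.80
SREBF2	FASN	0	0	0	0.25	0	0.55	0.86	0.92
SREBF2	INSIG1	0	0	0	0	0.60	0.66	0.84	0.94
SREBF2	INSIG2	0	0	0	0	0.58	0.62	0.80	0.92
PPARG	CD36	0	0	0	0	0.40	0.70	0.90	0.95
PPARG	FABP3	0	0	0	0	0	0.60	0.85	0.90
PPARG	LPL	0	0	0	0	0	0.55	0.82	0.88
PPARG	ADFP	0	0	0	0	0	0	0.80	0.81
PPARG	SCD5	0	0	0	0	0	0.45	0.70	0.78
PPARG	PPARGC1A	0	0	0	0	0.72	0.80	0.90	0.97
PPARG	PPARGC1B	0	0	0	0	0.55	0.70	0.80	0.92
PPARG	ACACA	0	0	0	0	0	0	0.62	0.64
CD36	FABP3	0	0	0	0.35	0	0	0.68	0.76
CD36	LPL	0	0	0	0.28	0	0	0.75	0.80
LPL	FABP3	0	0	0	0	0	0	0.62	0.64
ACSS1	ACSS2	0	0	0	0.30	0	0.45	0.60	0.72
ACSS2	ACACA	0	0	0	0	0	0	0.60	0.65
ACSS2	ACSL1	0	0	0	0.18	0	0	0.45	0.52
ADFP	CD36	0	0	0	0	0	0	0.58	0.60
ADFP	LPL	0	0	0	0.15	0	0	0.52	0.56
ACSL1	CD36	0	0	0	0.22	0	0	0.60	0.68
ACSL1	FABP3	0	0	0	0.26	0	0	0.55	0.66
ACBP	ACSL1	0	0	0	0.20	0	0	0.48	0.55
DGAT1	DGAT2	0	0	0	0	0	0.60	0.75	0.85
DGAT1	GPAM	0	0	0	0	0	0.52	0.60	0.74
DGAT2	GPAM	0	0	0	0	0	0.52	0.58	0.72
AGPAT6	GPAM	0	0	0	0	0	0.58	0.50	0.75
AGPAT6	LPIN1	0	0	0	0	0	0.50	0.45	0.68
LPIN1	GPAM	0	0	0	0	0	0.55	0.62	0.76
OSBP	OSBPL2	0	0	0	0	0	0	0.50	0.52
OSBP	OSBPL10	0	0	0	0	0	0	0.46	0.48
SGPL1	SPHK2	0	0	0	0	0	0.55	0.70	0.80
SPTLC1	SPTLC2	0	0	0	0	0.70	0.75	0.85	0.96
SPTLC1	SGPL1	0	0	0	0	0	0.40	0.55	0.66
SPTLC2	SGPL1	0	0	0	0	0	0.40	0.52	0.64
BDH1	OXCT1	0	0	0	0	0	0.45	0.58	0.70
BTN1A1	XDH	0	0	0	0	0.62	0	0.78	0.90
PLIN	ADFP	0	0	0	0	0	0.45	0.66	0.72
VLDLR	LPL	0	0	0	0	0	0	0.68	0.70
ABCA1	ABCG2	0	0	0	0	0	0	0.55	0.57
FADS1	FADS2	0	0	0.10	0	0	0.60	0.80	0.88
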