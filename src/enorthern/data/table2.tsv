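gene	bioprocess	tpm_ma	tpm_s	tpm_mu
ACBP	fatty_acid_activation_transport	64	118	86
ACSL1	fatty_acid_activation_transport	172	295	363
ACSS1	fatty_acid_activation_transport	107	29	69
ACSS2	fatty_acid_activation_transport	226	29	69
ADFP	lipid_droplet_formation	474	295	51
CD36	fatty_acid_import	398	29	381
DGAT1	triacylglycerol_synthesis	32	88	17
FABP3	fatty_acid_activation_transport	755	29	69
FASN	fatty_acid_synthesis_desaturation	1499	531	17
GPAM	triacylglycerol_synthesis	312	29	51
INSIG1	transcription_regulation	194	59	17
LASS2	sphingolipid_synthesis	194	324	17
LPL	fatty_acid_import	690	118	138
OSBP	sphingolipid_synthesis	21	59	17
PLIN	lipid_droplet_formation	32	29	34
PPARG	transcription_regulation	75	177	17
SCAP	transcription_regulation	21	51	17
SCD5	fatty_acid_synthesis_desaturation	1661	324	51
SGPL1	sphingolipid_synthesis	10	177	34
SPTLC1	sphingolipid_synthesis	463	147	34
SREBF1	transcription_regulation	453	88	17
XDH	lipid_droplet_formation	1186	118	51
ABCA1	xenobiotic_cholesterol_transport	0	0	0
ABCG2	xenobiotic_cholesterol_transport	0	0	0
ACACA	fatty_acid_synthesis_desaturation	10	0	17
AGPAT6	triacylglycerol_synthesis	593	29	0
ASAHL	sphingolipid_synthesis	0	0	17
BDH1	ketone_body_utilization	0	118	51
BTN1A1	lipid_droplet_formation	744	0	0
DGAT2	triacylglycerol_synthesis	0	88	103
FADS1	fatty_acid_synthesis_desaturation	75	0	51
FADS2	fatty_acid_synthesis_desaturation	0	0	0
INSIG2	transcription_regulation	0	0	0
LPIN1	triacylglycerol_synthesis	0	0	138
OSBPL10	sphingolipid_synthesis	140	0	17
OSBPL2	sphingolipid_synthesis	0	88	0
OXCT1	ketone_body_utilization	10	0	0
PPARGC1A	transcription_regulation	21	0	51
PPARGC1B	transcription_regulation	0	0	0
SPHK2	sphingolipid_synthesis	0	0	0
SPTLC2	sphingolipid_synthesis	10	0	17
SREBF2	transcription_regulation	0	295	51
THRSP	transcription_regulation	0	29	69
UGCG	sphingolipid_synthesis	0	29	0
VLDLR	fatty_acid_import	0	0	34
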