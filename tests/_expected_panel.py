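"""Frozen expected derived statistics for the bundled 45-gene milk-fat panel.

Each row: (gene, pct_abundance, ratio_ma_s, e_r, status), with the derived
values at 3-decimal display precision and ``None`` for undefined cells.
These are the published reference values for the panel; the test suite
checks the pipeline reproduces every one of them.
"""

UP = "UP"
DOWN = "DOWN"
ND = "NOT_DIFFERENTIAL"
EXC = "EXCLUDED"

EXPECTED = [
    ("ACBP", 0.601, 0.542, 0.635, ND),
    ("ACSL1", 1.616, 0.583, 0.526, ND),
    ("ACSS1", 1.005, 3.690, 2.392, UP),
    ("ACSS2", 2.124, 7.793, 5.052, UP),
    ("ADFP", 4.454, 1.607, 3.864, UP),
    ("CD36", 3.740, 13.724, 3.786, UP),
    ("DGAT1", 0.301, 0.364, 0.827, ND),
    ("FABP3", 7.095, 26.034, 16.878, UP),
    ("FASN", 14.086, 2.823, 15.777, UP),
    ("GPAM", 2.932, 10.759, 8.113, UP),
    ("INSIG1", 1.823, 3.288, 6.126, UP),
    ("LASS2", 1.823, 0.599, 2.614, ND),
    ("LPL", 6.484, 5.847, 5.407, UP),
    ("OSBP", 0.197, 0.356, 0.663, ND),
    ("PLIN", 0.301, 1.103, 1.019, ND),
    ("PPARG", 0.705, 0.424, 1.367, ND),
    ("SCAP", 0.197, 0.412, 0.713, ND),
    ("SCD5", 15.608, 5.127, 12.921, UP),
    ("SGPL1", 0.094, 0.056, 0.129, DOWN),
    ("SPTLC1", 4.351, 3.150, 6.549, UP),
    ("SREBF1", 4.257, 5.148, 11.712, UP),
    ("XDH", 11.145, 10.051, 15.288, UP),
    ("ABCA1", 0.0, None, None, EXC),
    ("ABCG2", 0.0, None, None, EXC),
    ("ACACA", 0.094, None, None, EXC),
    ("AGPAT6", 5.572, 20.448, None, EXC),
    ("ASAHL", 0.0, None, None, EXC),
    ("BDH1", 0.0, None, 0.0, EXC),
    ("BTN1A1", 6.991, None, None, EXC),
    ("DGAT2", 0.0, None, 0.0, EXC),
    ("FADS1", 0.705, None, None, EXC),
    ("FADS2", 0.0, None, None, EXC),
    ("INSIG2", 0.0, None, None, EXC),
    ("LPIN1", 0.0, None, None, EXC),
    ("OSBPL10", 1.316, None, None, EXC),
    ("OSBPL2", 0.0, None, None, EXC),
    ("OXCT1", 0.094, None, None, EXC),
    ("PPARGC1A", 0.197, None, None, EXC),
    ("PPARGC1B", 0.0, None, None, EXC),
    ("SPHK2", 0.0, None, None, EXC),
    ("SPTLC2", 0.094, None, None, EXC),
    ("SREBF2", 0.0, None, 0.0, EXC),
    ("THRSP", 0.0, None, 0.0, EXC),
    ("UGCG", 0.0, None, None, EXC),
    ("VLDLR", 0.0, None, None, EXC),
]

UP_GENES = sorted(g for g, *_rest in EXPECTED if _rest[-1] == UP)
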