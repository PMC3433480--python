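ob_threshold	n_compounds	percent
90	6	1.88
80	15	4.69
70	31	9.69
60	53	16.56
50	90	28.13
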