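pathway	n_compounds
PPAR Signaling Pathway	60
Glucocorticoid and Inflammatory Pathway	58
L-arginine/NO Signaling Pathway	57
Renin-Angiotensin-Aldosterone System	35
Platelet Aggregation Pathway	31
TGF-beta Signaling Pathway	13
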