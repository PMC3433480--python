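target_id	short_name	gene_name	pdb_id	cvd_related	diseases	pathways
ACE	ACE	ACE	1UZF	1	Coronary artery disease;Arteriosclerosis;Hypertension;Heart failure;Hypokinesia;Stroke;Thromboembolism
ACE2	ACE2	ACE2	1R4L	1	Hypertension;Cardiovascular diseases
AKR1B1	Aldose reductase	AKR1B1	2DUX	1	Cardiovascular diseases;Diabetes
AR	Androgen receptor	AR	1GS4	1	Cardiovascular diseases
ANG	Ang	ANG	1B1I	1	Cardiovascular diseases
CA2	CA2	CA2	1I9P	1	Hypertension
CASP3	Caspase-3	CASP3	1RHR	1	Venous thrombosis
CTSK	Cathepsin K	CTSK	1TU6	1	Atherosclerosis
CTSS	Cathepsin S	CTSS	1NPZ	1	Atherosclerosis
CMA1	Chymase	CMA1	1T31	1	Hypertension;Coronary artery disease
CYP2C9	CYP2C9	CYP2C9	1R9O	1	Coronary artery disease;Heart diseases;Hypertension;Thromboembolism
NOS3	eNOS	NOS3	3NOS	1	Angina pectoris;Thrombosis;Heart failure;Acute coronary syndrome;Cardiovascular diseases;Myocardial infarction;Hypertension
ESR1	ER-alpha	ESR1	1YIN	1	Hyperlipidemia;Coronary artery disease
ESR2	ER-beta	ESR2	1NDE	1	Hyperlipidemia;Coronary artery disease
SELE	E-selectin	SELE	1G1T	1	Hypertension
F10	F10	F10	1MQ6	1	Coronary artery disease
F2	F2	F2	1TA2	1	Myocardial infarction;Thromboembolism
F7	F7	F7	1DAN	1	Thromboembolism;Cardiovascular diseases
NR3C1	GR	NR3C1	1NHZ	1	Hypertension;Cardiovascular diseases
HMGCR	HMG-CoA reductase	HMGCR	3CD7	1	Myocardial infarction;Hyperlipidemias;Cardiovascular diseases;Arteriosclerosis;Hypertension
HSP90AA1	HSP90-alpha	HSP90AA1	1UYH	1	Arteriosclerosis;Acute coronary syndrome
HSP90AB1	HSP90-beta	HSP90AB1	1UYM	1	Arteriosclerosis;Acute coronary syndrome
NOS2	iNOS	NOS2	1NSI	1	Hypertension
NR1H3	LXR-alpha	NR1H3	1UHL	1	Cardiovascular diseases;Hypertension;Coronary artery disease
NR1H2	LXR-beta	NR1H2	1PQ6	1	Hypertension;Cardiovascular diseases
MIF	MIF	MIF	1GCZ	1	Arteriosclerosis
MMP9	MMP-9	MMP9	1GKD	1	Coronary artery disease;Heart failure
SOD2	Mn-SOD	SOD2	1XDC	1	Arteriosclerosis;Hyperlipidemia
NR3C2	MR	NR3C2	2AA5	1	Hypertension;Hyperlipidemias
PDE4D	PDE4D	PDE4D	1Y2K	1	Heart failure;Arrhythmia
PPARA	PPAR-alpha	PPARA	1K7L	1	Hypertension;Coronary artery disease;Hyperlipidemias;Cardiovascular diseases
PPARD	PPAR-delta	PPARD	1Y0S	1	Venous thrombosis;Hyperlipidemias
PPARG	PPAR-gamma	PPARG	1RDT	1	Hypertension;Cardiovascular diseases;Hyperlipidemias
RBP4	RBP-4	RBP4	1RBP	1	Coronary artery disease;Arteriosclerosis;Hypertension;Hyperlipidemia
REN	Renin	REN	2IKO	1	Coronary artery disease;Arteriosclerosis;Hypertension;Hyperlipidemia;Heart failure
RXRA	RXR-alpha	RXRA	1FBY	1	Hypertension;Cardiovascular diseases
RXRB	RXR-beta	RXRB	1H9U	1	Hypertension;Cardiovascular diseases
PLA2G2A	sPLA2-IIA	PLA2G2A	1KQU	1	Myocardial infarction;Coronary artery disease
TGFBR1	TGF-beta1R	TGFBR1	1RW8	1	Cardiovascular diseases;Hypertension
VDR	VDR	VDR	1DB1	1	Cardiovascular diseases;Hypertension
KDR	VEGFR-2	KDR	2OH4	1	Hypertension
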