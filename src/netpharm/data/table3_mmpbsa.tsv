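complex_id	term	mean	std
REN-94	e_ele	-7.65	3.86
REN-94	e_vdw	-26.11	2.62
REN-94	g_np	-4.17	0.24
REN-94	g_pb	8.12	1.55
REN-94	e_gas	-33.76	3.79
REN-94	g_sol	3.95	1.49
REN-94	minus_t_ds	15.88	7.35
REN-94	g_bind_no_entropy	-29.81	2.67
REN-94	g_bind_with_entropy	-27.14
REN-15	e_ele	-16.05	5.45
REN-15	e_vdw	-32.50	2.45
REN-15	g_np	-5.17	0.27
REN-15	g_pb	17.06	2.79
REN-15	e_gas	-48.54	5.71
REN-15	g_sol	11.89	2.71
REN-15	minus_t_ds	13.91	7.06
REN-15	g_bind_no_entropy	-36.65	3.75
REN-15	g_bind_with_entropy	-22.74
VDR-176	e_ele	-5.48	1.77
VDR-176	e_vdw	-41.68	2.38
VDR-176	g_np	-5.53	0.09
VDR-176	g_pb	12.91	1.26
VDR-176	e_gas	-47.15	3.40
VDR-176	g_sol	7.38	1.28
VDR-176	minus_t_ds	18.53	5.91
VDR-176	g_bind_no_entropy	-39.77	3.17
VDR-176	g_bind_with_entropy	-21.24
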