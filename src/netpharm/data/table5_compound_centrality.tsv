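compound_id	betweenness	degree	known_active
M2	1.9130	3	0
M13	724.1483	25	0
M15	180.7998	13	1
M17	21.6577	5	0
M18	112.4945	11	0
M21	359.3636	14	0
M36	111.0346	12	0
M53	16.4952	4	0
M61	16.2719	5	0
M66	68.6507	10	0
M67	19.2309	5	0
M68	291.2255	19	1
M69	350.7039	20	1
M80	60.3365	9	1
M87	69.4337	10	0
M88	43.5437	7	0
M91	123.2400	13	0
M94	14.2769	4	0
M95	0.0000	1	0
M98	7.4776	4	0
M99	147.0782	14	0
M106	230.6302	15	1
M107	0.6961	2	0
M109	244.4809	18	1
M110	61.3330	10	1
M117	518.7937	21	0
M122	13.3008	4	0
M123	51.7626	8	1
M128	448.0906	20	0
M139	342.8197	18	0
M141	242.6144	13	1
M148	169.9105	12	1
M151	390.0531	16	1
M156	116.6271	11	0
M157	198.5621	13	0
M167	10.6765	5	0
M172	31.7887	7	0
M176	48.0524	8	1
M177	293.8129	16	1
M180	80.7252	10	1
M189	18.8204	5	0
M193	35.0662	6	0
M205	1.0506	2	0
M206	0.7509	2	0
M217	0.0000	1	0
M227	4.6731	4	0
M230	455.5151	9	1
M233	116.7896	13	1
M234	61.1274	10	1
M235	93.3910	9	1
M236	24.0610	5	0
M237	26.0983	6	0
M238	9.0711	5	0
M239	15.1011	5	0
M240	24.9245	6	0
M241	92.3841	8	1
M242	104.5600	10	1
M243	67.0867	7	0
M244	52.0521	7	0
M245	16.8538	6	0
M246	45.1483	5	0
M247	2.3093	3	0
M248	0.0000	1	0
M249	26.8981	6	0
M250	37.1891	7	0
M252	17.6270	3	0
M258	100.4710	5	0
M259	90.7898	11	0
M286	62.3123	9	0
M293	45.8579	9	0
M294	138.5526	13	1
M295	67.9490	9	1
M300	47.3511	9	0
M301	10.6174	4	0
M302	5.9018	4	0
M305	23.6586	7	0
M314	44.8343	8	0
M316	86.7339	9	0
M320	7.3409	3	0
M322	12.8785	4	0
M326	2.1035	2	0
M327	1.7637	2	0
M329	28.0748	6	0
M331	437.6101	22	0
MCK	144.5436	13	1
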