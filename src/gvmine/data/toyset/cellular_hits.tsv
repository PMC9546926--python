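s01_o1	sp1	40.0	95	50	2	1	100	5	99	1e-20	120.0	Bacteria
s01_o3	sp2	34.9	50	30	1	1	50	1	50	1e-20	90.0	Bacteria
s02_o1	sp3	90.0	100	10	0	1	100	1	100	1e-04	35.0	Bacteria
s02_o1	sp4	35.0	100	60	3	1	100	1	100	1e-05	42.0	Bacteria
s02_o1	sp5	50.0	100	48	1	1	100	1	100	1e-30	160.0	Eukaryota
s04_o1	sp6	60.0	290	110	4	1	300	1	290	1e-50	260.0	Archaea
s04_o1	sp7	55.0	280	120	5	1	290	1	280	1e-12	88.0	Bacteria
s05_o2	sp8	45.0	48	25	1	1	50	1	48	1e-08	55.0	Eukaryota
s07_o1	sp9	38.0	390	230	8	1	400	1	390	1e-06	48.0	Bacteria
s09_o1	sp10	70.0	490	140	2	1	500	1	490	1e-33	200.0	Viruses
s11_o1	sp11	42.0	195	110	4	1	200	1	195	1e-22	130.0	Bacteria
s11_o1	sp12	41.0	190	108	4	5	200	1	190	1e-21	125.0	Bacteria
s11_o2	sp13	39.0	98	58	2	1	100	1	98	1e-09	58.0	Eukaryota
s12_o1	sp14	36.0	480	300	9	1	500	1	480	2e-06	47.0	Bacteria
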