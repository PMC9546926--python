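orf_id	scaffold_id	start	end	strand	aa_length
s01_o1	s01	100	400	+	100
s01_o2	s01	500	647	+	49
s01_o3	s01	700	850	-	50
s02_o1	s02	0	300	+	100
s02_o2	s02	400	490	+	30
s04_o1	s04	10	910	+	300
s05_o1	s05	100	1600	+	500
s05_o2	s05	2000	2150	+	50
s07_o1	s07	100	1300	+	400
s07_o2	s07	1500	1560	-	20
s07_o3	s07	2000	3200	+	400
s08_o1	s08	0	150	+	50
s09_o1	s09	300	1800	+	500
s09_o2	s09	2000	2147	-	49
s11_o1	s11	50	650	+	200
s11_o2	s11	700	1000	+	100
s12_o1	s12	100	1600	+	500
s12_o2	s12	2000	3500	+	500
s12_o3	s12	4000	4135	+	45
s12_o4	s12	5000	5600	+	200
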