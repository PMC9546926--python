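scaffold_id	marker_id	orf_id	evalue	bitscore
s12	PolB	s12_o1	1e-50	800
s12	PolB	s12_o2	1e-20	300
s07	PolB	s07_o1	1e-40	700
s07	PolB	s07_o3	1e-12	200
s01	PolB	s01_o1	1e-30	500
s09	PolB	s09_o1	1e-35	600
s12	MCP	s12_o4	1e-15	250
s12	VLTF3	s12_o2	1e-18	300
s07	VLTF3	s07_o3	1e-08	100
s07	A32	s07_o1	1e-06	80
s01	MCP	s01_o3	1e-04	40
s05	MCP	s05_o1	1e-09	90
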