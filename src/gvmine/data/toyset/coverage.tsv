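scaffold_id	sample_id	mean_coverage	covered_length
s01	A	10.0	15000
s02	A	5.0	10000
s04	A	2.0	10001
s07	A	8.0	45000
s12	A	20.0	99000
s03	A	7.0	9999
s09	B	4.0	29000
s12	B	1.0	10500
s01	B	0.5	8000
s05	B	3.0	20000
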