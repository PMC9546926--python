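scaffold_id	length
s01	15000
s02	12000
s03	9999
s04	10000
s05	22000
s06	8000
s07	50000
s08	10500
s09	30000
s10	5000
s11	18000
s12	100000
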