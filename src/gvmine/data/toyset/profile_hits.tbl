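# hand-written per-sequence profile search table for the toy example
# target  accession  query  accession  evalue  score  bias
s01_o1 - NCVOG0038 - 1e-30 250.1 0.0
s01_o1 - NCVOG0023 - 1e-12 80.5 0.0
s01_o3 - NCVOG0038 - 1e-10 45.0 0.0
s02_o1 - NCVOG0038 - 1e-09 38.2 0.0
s05_o1 - NCVOG0271 - 1e-40 310.0 0.1
s05_o1 - NCVOG0271 - 1e-35 290.0 0.1
s07_o1 - NCVOG0038 - 1e-25 200.0 0.0
s07_o3 - NCVOG1117 - 1e-15 98.7 0.0
s09_o1 - NCVOG0271 - 1e-60 450.0 0.2
s12_o1 - NCVOG0038 - 1e-50 400.0 0.0
s12_o2 - NCVOG0262 - 1e-22 150.3 0.0
s12_o4 - NCVOG1117 - 1e-11 60.1 0.0
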