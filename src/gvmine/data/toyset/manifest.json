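{
  "n_scaffolds": 12,
  "scaffolds_ge_10kb": 9,
  "orf_rows": 20,
  "orfs_min_50aa": 15,
  "profile_hit_rows": 12,
  "profile_hits_retained": 10,
  "cellular_hit_rows": 14,
  "cellular_hits_retained": 11,
  "classified_viral": 3,
  "marker_hit_rows": 12,
  "marker_hits_within_initial_cutoff": 11,
  "high_confidence_scaffolds": 2,
  "extended_scaffolds": 5,
  "coverage_rows": 10,
  "present_calls": 7,
  "shared_between_samples": 1
}
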