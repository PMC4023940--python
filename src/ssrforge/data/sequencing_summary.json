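{
  "description": "Published summary counts from the adzuki bean weevil (Callosobruchus chinensis) microsatellite-development survey: per-lane raw/clean read counts, final-assembly base composition, and the primer validation screen tallies.",
  "lanes": {
    "Bpis1": {"raw_reads": 52566784, "clean_reads": 46595197},
    "Bpis2": {"raw_reads": 54321240, "clean_reads": 47965654}
  },
  "genome_base_counts": {
    "A": 157892519,
    "T": 157873741,
    "C": 90693363,
    "G": 90665162,
    "N": 0
  },
  "primer_screen": {
    "tested": 500,
    "amplified": 403,
    "expected_size": 365,
    "polymorphic": 196
  }
}
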