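{
 "foldbacks": 7,
 "independence_flagged": 30,
 "independence_scorable": 30,
 "metrics": {
  "chains": {
   "precision": 1.0,
   "recall": 1.0
  },
  "foldbacks": {
   "precision": 1.0,
   "recall": 1.0
  },
  "sister_parallel_pairs": {
   "precision": 1.0,
   "recall": 1.0
  },
  "tiles": {
   "precision": 1.0,
   "recall": 1.0
  }
 },
 "pairs_by_class": {
  "breakpoints": 120,
  "gapped": 46,
  "insertion_overlap": 1,
  "parallel": 30,
  "parallel_groups": 30
 }
}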