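{
 "profile": "tiny",
 "n": 50,
 "seed": 20010,
 "hand_recomputed_obs": {
  "0": {
   "total": 20,
   "dietary": 15,
   "lifestyle": 5
  },
  "1": {
   "total": 22,
   "dietary": 15,
   "lifestyle": 7
  },
  "2": {
   "total": 16,
   "dietary": 13,
   "lifestyle": 3
  },
  "3": {
   "total": 28,
   "dietary": 21,
   "lifestyle": 7
  },
  "4": {
   "total": 9,
   "dietary": 5,
   "lifestyle": 4
  }
 },
 "hand_recomputed_totals": [
  20,
  22,
  16,
  28,
  9,
  21,
  16,
  14,
  26,
  8,
  25,
  21,
  27,
  29,
  22,
  13,
  25,
  11,
  25,
  14,
  18,
  22,
  16,
  19,
  9,
  26,
  14,
  25,
  29,
  15,
  18,
  20,
  26,
  20,
  12,
  20,
  22,
  17,
  23,
  26,
  20,
  29,
  12,
  18,
  27,
  24,
  26,
  15,
  20,
  16
 ]
}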