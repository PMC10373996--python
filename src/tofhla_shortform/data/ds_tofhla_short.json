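{
 "intercept": 23,
 "weights": {
  "R2": 2,
  "R3": 5,
  "R13": 1,
  "R14": 7,
  "R18": 4,
  "R19": 4,
  "R20": 2,
  "R21": 5,
  "R23": 4,
  "R24": 5,
  "R25": 8,
  "R37": 3,
  "R38": 3,
  "R39": 0,
  "R40": 4,
  "R41": 2,
  "R42": 0,
  "R43": 6,
  "R44": 5,
  "R45": 2
 },
 "scale": {
  "inadequate_max": 59,
  "marginal_max": 74,
  "score_max": 100
 },
 "provenance": "published 20-item reading-only short form (DS-TOFHLA)"
}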