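{
 "electronic_tag_recoveries.csv": {
  "sha256": "990c8c9c0ad445e396d9b35f3c74b3b878d167230e1cc721954c0144b847c8eb",
  "rows": 48
 },
 "mark_recapture.csv": {
  "sha256": "8361b3478e77766dfd7c78c2bd1d26203cebd7723d8c414bd2d5ecb72b2f82e2",
  "rows": 6
 }
}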