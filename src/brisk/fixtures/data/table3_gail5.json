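{
 "name": "table3_gail5",
 "kind": "calibration",
 "model": "Gail 5-year risk",
 "horizon": "five_year",
 "bands": [
  "< 45",
  "45-49",
  "50-54",
  "55-59",
  "60-64",
  "65-69",
  "70-74",
  "75+"
 ],
 "n": [
  24,
  180,
  273,
  342,
  441,
  317,
  97,
  26
 ],
 "expected": [
  0.2,
  1.7,
  3.19,
  4.8,
  7.67,
  6.02,
  1.9,
  0.53
 ],
 "observed": [
  0.23,
  2.06,
  3.58,
  5.3,
  8.76,
  7.68,
  2.52,
  0.63
 ],
 "printed": {
  "total_expected": 26.01,
  "total_observed": 30.75,
  "ratio": 0.85,
  "ci": [
   0.58,
   1.24
  ]
 }
}
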