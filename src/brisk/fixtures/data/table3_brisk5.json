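{
 "name": "table3_brisk5",
 "kind": "calibration",
 "model": "BRISK 5-year risk",
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
  0.32,
  2.27,
  4.13,
  6.89,
  9.13,
  6.51,
  1.74,
  0.78
 ],
 "observed": [
  0.23,
  2.06,
  3.58,
  5.3,
  8.76,
  7.68,
  2.5,
  0.63
 ],
 "printed": {
  "total_expected": 31.78,
  "total_observed": 30.74,
  "ratio": 1.03,
  "ci": [
   0.73,
   1.46
  ]
 }
}
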