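{
 "name": "table3_brisklt",
 "kind": "calibration",
 "model": "BRISK remaining lifetime risk",
 "horizon": "lifetime",
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
  4.28,
  23.67,
  32.54,
  41.1,
  37.52,
  18.78,
  3.33,
  0.6
 ],
 "observed": [
  3.23,
  22.9,
  32.28,
  35.96,
  39.54,
  22.12,
  4.42,
  0.51
 ],
 "printed": {
  "total_expected": 161.83,
  "total_observed": 160.96,
  "ratio": 1.01,
  "ci": [
   0.86,
   1.17
  ]
 }
}
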