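{
 "name": "table3_ibislt",
 "kind": "calibration",
 "model": "IBIS v7 remaining lifetime risk",
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
  2.78,
  17.25,
  22.64,
  23.79,
  26.94,
  14.49,
  3.62,
  0.66
 ],
 "observed": [
  3.58,
  23.24,
  30.32,
  33.26,
  38.01,
  20.3,
  5.11,
  0.76
 ],
 "printed": {
  "total_expected": 112.18,
  "total_observed": 154.59,
  "ratio": 0.73,
  "ci": [
   0.6,
   0.87
  ]
 }
}
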