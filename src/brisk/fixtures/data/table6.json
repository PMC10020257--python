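{
 "name": "table6",
 "kind": "reclassification",
 "scheme": "five_year",
 "old_model": "Gail 5-year risk",
 "new_model": "BRISK 5-year risk",
 "arms": {
  "cases": {
   "matrix": [
    [
     5,
     8,
     7,
     5
    ],
    [
     14,
     9,
     12,
     18
    ],
    [
     4,
     8,
     10,
     27
    ],
    [
     1,
     1,
     5,
     6
    ]
   ],
   "row_totals": [
    25,
    53,
    49,
    13
   ],
   "col_totals": [
    24,
    26,
    34,
    56
   ],
   "total": 140
  }
 },
 "printed": {
  "case_improvement": 0.314,
  "se_case": 0.07
 }
}
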