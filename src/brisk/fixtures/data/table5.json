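{
 "name": "table5",
 "kind": "reclassification",
 "scheme": "five_year",
 "old_model": "Gail 5-year risk",
 "new_model": "BRISK 5-year risk",
 "arms": {
  "cases": {
   "matrix": [
    [
     15,
     11,
     15,
     32
    ],
    [
     50,
     47,
     77,
     162
    ],
    [
     22,
     33,
     51,
     129
    ],
    [
     3,
     1,
     7,
     52
    ]
   ],
   "row_totals": [
    73,
    336,
    235,
    63
   ],
   "col_totals": [
    90,
    92,
    150,
    375
   ],
   "total": 707
  }
 },
 "printed": {
  "case_improvement": 0.438,
  "se_case": 0.029
 }
}
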