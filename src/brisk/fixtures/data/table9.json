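{
 "name": "table9",
 "kind": "reclassification",
 "scheme": "lifetime",
 "old_model": "IBIS v7 remaining lifetime risk",
 "new_model": "BRISK remaining lifetime risk",
 "arms": {
  "cases": {
   "matrix": [
    [
     5,
     3,
     3,
     0,
     4
    ],
    [
     11,
     15,
     15,
     8,
     12
    ],
    [
     4,
     7,
     4,
     4,
     8
    ],
    [
     0,
     0,
     1,
     0,
     2
    ],
    [
     0,
     0,
     0,
     0,
     0
    ]
   ],
   "row_totals": [
    15,
    61,
    27,
    3,
    0
   ],
   "col_totals": [
    20,
    25,
    23,
    12,
    26
   ],
   "total": 106
  }
 },
 "printed": {
  "case_improvement": 0.34,
  "se_case": 0.079
 }
}
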