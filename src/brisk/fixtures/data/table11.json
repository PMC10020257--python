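{
 "name": "table11",
 "kind": "reclassification",
 "scheme": "lifetime",
 "old_model": "IBIS v7 remaining lifetime risk",
 "new_model": "BRISK remaining lifetime risk",
 "arms": {
  "cases": {
   "matrix": [
    [
     9,
     11,
     4,
     1,
     5
    ],
    [
     23,
     35,
     37,
     12,
     44
    ],
    [
     3,
     15,
     7,
     7,
     20
    ],
    [
     0,
     0,
     2,
     0,
     3
    ],
    [
     0,
     0,
     0,
     0,
     1
    ]
   ],
   "row_totals": [
    30,
    151,
    52,
    5,
    1
   ],
   "col_totals": [
    35,
    61,
    50,
    20,
    73
   ],
   "total": 239
  }
 },
 "printed": {
  "case_improvement": 0.423,
  "se_case": 0.05
 }
}
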