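{
 "name": "table8",
 "kind": "reclassification",
 "scheme": "lifetime",
 "old_model": "IBIS v7 remaining lifetime risk",
 "new_model": "BRISK remaining lifetime risk",
 "arms": {
  "cases": {
   "matrix": [
    [
     29,
     23,
     5,
     2,
     8
    ],
    [
     53,
     74,
     72,
     31,
     136
    ],
    [
     11,
     22,
     21,
     9,
     44
    ],
    [
     2,
     3,
     5,
     1,
     6
    ],
    [
     0,
     0,
     1,
     0,
     4
    ]
   ],
   "row_totals": [
    67,
    366,
    107,
    17,
    5
   ],
   "col_totals": [
    95,
    122,
    104,
    43,
    198
   ],
   "total": 562
  }
 },
 "printed": {
  "case_improvement": 0.425,
  "se_case": 0.0324
 }
}
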