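{
 "name": "table10",
 "kind": "reclassification",
 "scheme": "lifetime",
 "old_model": "IBIS v7 remaining lifetime risk",
 "new_model": "BRISK remaining lifetime risk",
 "arms": {
  "cases": {
   "matrix": [
    [
     25,
     17,
     4,
     1,
     6
    ],
    [
     48,
     65,
     57,
     29,
     109
    ],
    [
     9,
     17,
     17,
     5,
     35
    ],
    [
     2,
     3,
     4,
     1,
     6
    ],
    [
     0,
     0,
     1,
     0,
     5
    ]
   ],
   "row_totals": [
    53,
    308,
    83,
    16,
    6
   ],
   "col_totals": [
    84,
    102,
    83,
    36,
    161
   ],
   "total": 466
  }
 },
 "printed": {
  "case_improvement": 0.397,
  "se_case": 0.036
 }
}
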