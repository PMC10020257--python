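{
 "name": "table4",
 "kind": "reclassification",
 "scheme": "five_year",
 "old_model": "Gail 5-year risk",
 "new_model": "BRISK 5-year risk",
 "arms": {
  "cases": {
   "matrix": [
    [
     25,
     28,
     31,
     39
    ],
    [
     92,
     70,
     115,
     234
    ],
    [
     37,
     54,
     79,
     228
    ],
    [
     6,
     2,
     15,
     76
    ]
   ],
   "row_totals": [
    123,
    511,
    398,
    99
   ],
   "col_totals": [
    160,
    154,
    240,
    577
   ],
   "total": 1131
  },
  "controls": {
   "matrix": [
    [
     96,
     34,
     41,
     36
    ],
    [
     231,
     146,
     163,
     229
    ],
    [
     131,
     117,
     134,
     209
    ],
    [
     14,
     21,
     23,
     75
    ]
   ],
   "row_totals": [
    207,
    769,
    591,
    133
   ],
   "col_totals": [
    472,
    318,
    361,
    549
   ],
   "total": 1700
  }
 },
 "printed": {
  "overall_nri": 0.31,
  "case_improvement": 0.415,
  "control_improvement": -0.103,
  "se_overall": 0.031,
  "se_case": 0.023,
  "se_control": 0.021
 }
}
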