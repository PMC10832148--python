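{
 "purities": [
  0.15,
  0.35,
  0.55,
  0.75,
  0.9
 ],
 "coverages": [
  20.0,
  45.0,
  70.0,
  95.0,
  120.0
 ],
 "epsilons": [
  0.01,
  0.02,
  0.03,
  0.04,
  0.05,
  0.06,
  0.07,
  0.08,
  0.09,
  0.1
 ],
 "passes": [
  [
   [
    3,
    6,
    4,
    2,
    4,
    3,
    5,
    2,
    5,
    4
   ],
   [
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ],
   [
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ],
   [
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ],
   [
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ]
  ],
  [
   [
    0,
    0,
    0,
    0,
    0,
    1,
    0,
    0,
    0,
    0
   ],
   [
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ],
   [
    1,
    0,
    1,
    0,
    0,
    1,
    0,
    0,
    1,
    0
   ],
   [
    0,
    1,
    0,
    0,
    1,
    2,
    1,
    0,
    0,
    0
   ],
   [
    1,
    1,
    1,
    1,
    0,
    1,
    1,
    0,
    0,
    0
   ]
  ],
  [
   [
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ],
   [
    2,
    0,
    1,
    1,
    0,
    2,
    0,
    0,
    0,
    0
   ],
   [
    0,
    2,
    1,
    1,
    0,
    2,
    1,
    0,
    1,
    2
   ],
   [
    0,
    0,
    0,
    0,
    1,
    1,
    0,
    0,
    1,
    2
   ],
   [
    0,
    0,
    0,
    0,
    3,
    1,
    1,
    1,
    0,
    0
   ]
  ],
  [
   [
    0,
    0,
    0,
    1,
    3,
    0,
    1,
    0,
    1,
    3
   ],
   [
    1,
    1,
    1,
    2,
    2,
    2,
    1,
    2,
    2,
    0
   ],
   [
    2,
    4,
    1,
    2,
    2,
    0,
    1,
    2,
    1,
    1
   ],
   [
    0,
    0,
    2,
    5,
    3,
    5,
    2,
    1,
    1,
    2
   ],
   [
    1,
    2,
    1,
    1,
    2,
    1,
    2,
    1,
    1,
    2
   ]
  ],
  [
   [
    1,
    1,
    3,
    2,
    1,
    2,
    0,
    2,
    4,
    7
   ],
   [
    1,
    0,
    3,
    1,
    5,
    3,
    2,
    1,
    1,
    5
   ],
   [
    2,
    4,
    2,
    1,
    1,
    2,
    2,
    2,
    6,
    2
   ],
   [
    0,
    1,
    3,
    0,
    1,
    4,
    1,
    2,
    3,
    7
   ],
   [
    1,
    0,
    2,
    2,
    1,
    3,
    1,
    3,
    2,
    3
   ]
  ]
 ],
 "reps": 10,
 "seed": 20260101,
 "sim": {
  "n_chromosomes": 4,
  "muts_per_mb": 2.0
 }
}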