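{
 "construct": "WT",
 "drug": {
  "kd": 156.0,
  "kon_c": 0.00010541635474245374,
  "kon_i": 1.7782794100389227e-07,
  "kon_o": 1e-05,
  "m_act": 0.2,
  "m_is": 1.0,
  "m_oif": 0.2818,
  "m_rec": 0.013876172237820422,
  "phi": 65.0
 },
 "gna": 10.0,
 "late_scale": 0.4534111281989978,
 "laws": {
  "a3": {
   "A": 4.724437695264101,
   "B": 22.5
  },
  "act1": {
   "A": 7.178723320925743,
   "B": 24.038461538461537
  },
  "act2": {
   "A": 8.478398338552502,
   "B": 24.038461538461537
  },
  "act3": {
   "A": 14.386506690014329,
   "B": 28.57142857142857
  },
  "ax": {
   "A": 3.9427683727353746,
   "B": 39.19540521927711
  },
  "ay": {
   "A": 2.688637992577505,
   "B": 19.893754779075024
  },
  "b3": {
   "A": 0.000475801296927914,
   "B": -15.000000000000004
  },
  "bx": {
   "A": 7.248611115282452e-05,
   "B": -18.573794813660836
  },
  "by": {
   "A": 0.00045226099649819826,
   "B": -14.552619989483354
  },
  "dea1": {
   "A": 0.2301835043412596,
   "B": -26.041666666666668
  },
  "dea2": {
   "A": 0.19740882570981458,
   "B": -26.041666666666668
  },
  "dea3": {
   "A": 0.4344348586261127,
   "B": -28.57142857142857
  },
  "del": {
   "A": 2.3014091320055623e-05,
   "B": -24.173310841716663
  },
  "gam": {
   "A": 0.8458425574174622,
   "B": 22.301371045199943
  },
  "ise": {
   "A": 0.0013672929211029734,
   "B": -56.87410359111805
  },
  "isx": {
   "A": 0.01652883429973874,
   "B": 56.63413406368556
  },
  "oif": {
   "A": 2.8,
   "B": 1000000000.0
  }
 },
 "schema_version": 1,
 "w1": 0.6024050772687819,
 "w2": 1.0
}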