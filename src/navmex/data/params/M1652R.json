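{
 "construct": "M1652R",
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
 "gna": 19.5,
 "late_scale": 3.340216463393012,
 "laws": {
  "a3": {
   "A": 2.0214567841298448,
   "B": 20.0
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
   "A": 1.1299043623254863,
   "B": 16.92803429200332
  },
  "ay": {
   "A": 0.15901106371901452,
   "B": 24.895532193449665
  },
  "b3": {
   "A": 0.0010118464045678953,
   "B": -16.363636363636363
  },
  "bx": {
   "A": 8.354814085132165e-08,
   "B": -15.087300049993697
  },
  "by": {
   "A": 0.0018974984767504734,
   "B": -18.55342011434754
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
   "A": 2.966455293824697e-05,
   "B": -20.083339055706
  },
  "gam": {
   "A": 1.0053595166789406,
   "B": 21.446762496652042
  },
  "ise": {
   "A": 0.007899518312418212,
   "B": -22.508003166231575
  },
  "isx": {
   "A": 0.002435257620454865,
   "B": 77.51048219257801
  },
  "oif": {
   "A": 2.8,
   "B": 1000000000.0
  }
 },
 "schema_version": 1,
 "w1": 0.44377799739671103,
 "w2": 1.0
}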