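{
 "construct": "R1626P",
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
 "gna": 12.2,
 "late_scale": 4.966682395248,
 "laws": {
  "a3": {
   "A": 5.4568308956340426,
   "B": 22.83723913115256
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
   "A": 0.5381582453082093,
   "B": 49.79805257452367
  },
  "ay": {
   "A": 5.4568308956340426,
   "B": 22.83723913115256
  },
  "b3": {
   "A": 1.6977867796634456e-06,
   "B": -11.628303434519369
  },
  "bx": {
   "A": 5.176553206011826e-05,
   "B": -34.18039827532766
  },
  "by": {
   "A": 1.6977867796634456e-06,
   "B": -11.628303434519369
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
   "A": 1.3956800653769416e-05,
   "B": -28.45087214168832
  },
  "gam": {
   "A": 0.5767827796248918,
   "B": 17.304815409895536
  },
  "ise": {
   "A": 0.0018126103539160949,
   "B": -23.089612714872313
  },
  "isx": {
   "A": 0.009381276460000131,
   "B": 22.76325260903362
  },
  "oif": {
   "A": 2.8,
   "B": 1000000000.0
  }
 },
 "schema_version": 1,
 "w1": 0.5423298839042731,
 "w2": 1.0
}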