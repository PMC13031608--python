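{
 "intercept": 38.54,
 "alpha": 0.05,
 "factors": [
  {
   "name": "ZmPAL",
   "units": "mg/mL",
   "low": 1.5,
   "high": 2.25,
   "printed": {
    "coefficient": 8.35,
    "t_value": 2.92,
    "p_value": 0.027
   }
  },
  {
   "name": "At4CL4",
   "units": "mg/mL",
   "low": 1.5,
   "high": 2.25,
   "printed": {
    "coefficient": -2.5,
    "t_value": -0.87,
    "p_value": 0.416
   }
  },
  {
   "name": "GmCHS",
   "units": "mg/mL",
   "low": 1.25,
   "high": 1.88,
   "printed": {
    "coefficient": -8.77,
    "t_value": -3.06,
    "p_value": 0.022
   }
  },
  {
   "name": "MsCHR",
   "units": "mg/mL",
   "low": 1.25,
   "high": 1.88,
   "printed": {
    "coefficient": 7.62,
    "t_value": 2.66,
    "p_value": 0.037
   }
  },
  {
   "name": "ZmCHI",
   "units": "mg/mL",
   "low": 1.0,
   "high": 1.5,
   "printed": {
    "coefficient": -4.68,
    "t_value": -1.64,
    "p_value": 0.153
   }
  },
  {
   "name": "CoA",
   "units": "mM",
   "low": 1.5,
   "high": 2.25,
   "printed": {
    "coefficient": 3.99,
    "t_value": 1.39,
    "p_value": 0.213
   }
  },
  {
   "name": "ATP",
   "units": "mM",
   "low": 1.5,
   "high": 2.25,
   "printed": {
    "coefficient": 0.75,
    "t_value": 0.26,
    "p_value": 0.801
   }
  },
  {
   "name": "NADPH",
   "units": "mM",
   "low": 1.5,
   "high": 2.25,
   "printed": {
    "coefficient": -5.83,
    "t_value": -2.04,
    "p_value": 0.088
   }
  },
  {
   "name": "tyrosine",
   "units": "mM",
   "low": 2.0,
   "high": 3.0,
   "printed": {
    "coefficient": 5.73,
    "t_value": 2.0,
    "p_value": 0.092
   }
  },
  {
   "name": "pH",
   "units": "pH",
   "low": 6.0,
   "high": 8.0,
   "printed": {
    "coefficient": 7.07,
    "t_value": 2.47,
    "p_value": 0.048
   }
  },
  {
   "name": "temperature",
   "units": "degC",
   "low": 30.0,
   "high": 37.0,
   "printed": {
    "coefficient": 5.7,
    "t_value": 1.99,
    "p_value": 0.094
   }
  },
  {
   "name": "time",
   "units": "h",
   "low": 24.0,
   "high": 36.0,
   "printed": {
    "coefficient": -1.76,
    "t_value": -0.62,
    "p_value": 0.561
   }
  },
  {
   "name": "volume",
   "units": "uL",
   "low": 50.0,
   "high": 75.0,
   "printed": {
    "coefficient": 8.66,
    "t_value": 3.03,
    "p_value": 0.023
   }
  }
 ]
}
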