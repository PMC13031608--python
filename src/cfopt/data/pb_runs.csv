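run_id,round_id,ZmPAL,At4CL4,GmCHS,MsCHR,ZmCHI,CoA,ATP,NADPH,tyrosine,pH,temperature,time,volume,response_mg_L,replicate_sd,n_reps
PB01,0,1.5,2.25,1.25,1.88,1.0,2.25,2.25,2.25,3.0,6.0,30.0,36.0,75.0,50.43,0.05,3
PB02,0,2.25,2.25,1.25,1.88,1.5,1.5,1.5,1.5,2.0,8.0,30.0,36.0,50.0,52.41,1.96,3
PB03,0,2.25,2.25,1.25,1.25,1.5,2.25,1.5,2.25,3.0,6.0,30.0,24.0,50.0,14.24,1.81,3
PB04,0,1.5,1.5,1.25,1.88,1.0,2.25,1.5,2.25,3.0,8.0,37.0,24.0,50.0,76.42,2.82,3
PB05,0,1.5,1.5,1.25,1.25,1.5,1.5,2.25,1.5,3.0,8.0,37.0,36.0,50.0,37.36,5.58,3
PB06,0,2.25,2.25,1.88,1.25,1.0,2.25,2.25,1.5,3.0,8.0,30.0,24.0,50.0,65.37,3.20,3
PB07,0,1.5,2.25,1.88,1.25,1.5,2.25,1.5,1.5,2.0,6.0,37.0,24.0,75.0,17.45,2.40,3
PB08,0,1.5,1.5,1.88,1.88,1.0,2.25,2.25,1.5,2.0,6.0,30.0,36.0,50.0,13.96,0.71,3
PB09,0,1.5,1.5,1.88,1.25,1.5,1.5,2.25,2.25,3.0,8.0,30.0,24.0,75.0,20.86,4.09,3
PB10,0,1.5,2.25,1.88,1.25,1.0,1.5,1.5,2.25,2.0,8.0,30.0,36.0,75.0,11.41,0.92,3
PB11,0,2.25,2.25,1.88,1.88,1.0,1.5,2.25,2.25,2.0,8.0,37.0,24.0,50.0,26.45,1.04,3
PB12,0,1.5,1.5,1.25,1.25,1.0,1.5,1.5,1.5,2.0,6.0,30.0,24.0,50.0,15.60,2.24,3
PB13,0,2.25,1.5,1.88,1.88,1.0,1.5,1.5,1.5,3.0,6.0,37.0,24.0,75.0,78.59,8.76,3
PB14,0,2.25,1.5,1.88,1.88,1.5,2.25,1.5,1.5,3.0,8.0,30.0,36.0,75.0,66.55,2.24,3
PB15,0,2.25,2.25,1.25,1.25,1.0,1.5,2.25,1.5,3.0,6.0,37.0,36.0,75.0,71.43,2.81,3
PB16,0,1.5,2.25,1.88,1.88,1.5,1.5,1.5,2.25,3.0,6.0,37.0,36.0,50.0,15.94,2.37,3
PB17,0,2.25,1.5,1.88,1.25,1.5,2.25,2.25,2.25,2.0,6.0,37.0,36.0,50.0,17.81,0.46,3
PB18,0,1.5,2.25,1.25,1.88,1.5,2.25,2.25,1.5,2.0,8.0,37.0,24.0,75.0,79.64,1.95,3
PB19,0,2.25,1.5,1.25,1.88,1.5,1.5,2.25,2.25,2.0,6.0,30.0,24.0,75.0,58.01,4.77,3
PB20,0,2.25,1.5,1.25,1.25,1.0,2.25,1.5,2.25,2.0,8.0,37.0,36.0,75.0,75.77,5.78,3
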