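run_id,round_id,MsCHR,ZmPAL,GmCHS,volume,pH,response_mg_L,replicate_sd,n_reps
SA1,0,1.88,2.25,1.25,50,7.0,76.20,4.35,3
SA2,0,2.26,2.70,1.0,75,7.5,93.63,8.47,3
SA3,0,2.63,3.15,0.75,100,8.0,104.42,1.51,3
SA4,0,3.0,3.60,0.5,125,8.5,97.64,3.42,3
SA5,0,3.38,4.05,0.25,150,9.0,76.46,4.31,3
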