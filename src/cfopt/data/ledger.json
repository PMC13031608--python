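{
 "best_pb_yield_mg_L": {
  "value": 79.64,
  "sd": 1.95,
  "source": "two-level screening, run 18 (highest of 20 runs)"
 },
 "best_ascent_yield_mg_L": {
  "value": 104.42,
  "sd": 1.51,
  "source": "steepest-ascent trial 3 (highest of 5 trials)"
 },
 "ml_optimized_yield_mg_L": {
  "value": 155.32,
  "sd": 14.39,
  "source": "third active-learning round, best validated condition"
 },
 "scaffold_assembly_yield_mg_L": {
  "value": 439.42,
  "sd": 19.53,
  "source": "after scaffold-mediated enzyme assembly at 5 mg/mL scaffold"
 }
}
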