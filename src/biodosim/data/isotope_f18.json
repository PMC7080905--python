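{
  "name": "F-18",
  "half_life_min": 109.77,
  "mean_np_energy_mev": 0.2498,
  "beta_branching": 0.9686
}
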