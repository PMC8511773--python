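{
  "model": "rma",
  "description": "Rosenzweig-MacArthur predator-prey model with strong Allee effect; rates per year, densities per hectare; values estimated from Canada lynx / snowshoe hare data.",
  "r": 2.47,
  "c": 0.19,
  "alpha": 800.0,
  "beta": 1.5,
  "chi": 0.004,
  "delta": 2.2,
  "mu": 0.03,
  "nu": 0.003
}
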