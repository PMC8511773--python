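{
  "model": "may",
  "description": "May (Leslie-Gower) predator-prey model with strong Allee effect and alternative prey; rates per year, densities per hectare; values estimated from Canada lynx / snowshoe hare data.",
  "r": 2.0,
  "c": 0.22,
  "alpha": 505.0,
  "beta": 0.3,
  "s": 0.85,
  "q": 205.0,
  "mu": 0.03,
  "nu": 0.003,
  "eps": 0.031
}
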