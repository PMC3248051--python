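{
  "species": [
    {"name": "A", "initial_concentration": 1.0},
    {"name": "B", "initial_concentration": 0.5}
  ],
  "reactions": [
    {"reactants": {"A": 2}, "products": {"B": 1}, "k_forward": 1.0, "k_reverse": 1.0}
  ],
  "t_max": 20.0
}
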