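{
  "species": [
    {"name": "A", "initial_concentration": 2.0},
    {"name": "B", "initial_concentration": 0.5}
  ],
  "reactions": [
    {"reactants": {"A": 1}, "products": {"B": 1}, "k_forward": 2.0, "k_reverse": 1.0}
  ],
  "t_max": 3.0
}
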