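{
  "species": [
    {"name": "A", "initial_concentration": 1.0},
    {"name": "B", "initial_concentration": 0.8},
    {"name": "C", "initial_concentration": 0.6}
  ],
  "reactions": [
    {"reactants": {"A": 1}, "products": {"B": 1}, "k_forward": 1.1051709180756477, "k_reverse": 1.0},
    {"reactants": {"B": 1}, "products": {"C": 1}, "k_forward": 1.1051709180756477, "k_reverse": 1.0},
    {"reactants": {"C": 1}, "products": {"A": 1}, "k_forward": 1.1051709180756477, "k_reverse": 1.0}
  ],
  "t_max": 10.0,
  "perturbations": [
    {"species": "A", "pi": 99.0}
  ]
}
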