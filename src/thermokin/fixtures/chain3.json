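{
  "species": [
    {"name": "A", "initial_concentration": 2.0},
    {"name": "B", "initial_concentration": 0.5},
    {"name": "C", "initial_concentration": 0.5},
    {"name": "D", "initial_concentration": 0.5}
  ],
  "reactions": [
    {"reactants": {"A": 1}, "products": {"B": 1}, "k_forward": 3.0, "k_reverse": 1.0},
    {"reactants": {"B": 1}, "products": {"C": 1}, "k_forward": 2.0, "k_reverse": 1.5},
    {"reactants": {"C": 1}, "products": {"D": 1}, "k_forward": 0.8, "k_reverse": 1.2}
  ],
  "t_max": 8.0,
  "perturbations": [
    {"species": "A", "pi": 198.0},
    {"species": "D", "pi": -0.495}
  ]
}
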