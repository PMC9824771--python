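{
  "kind": "type2",
  "threshold": 0.5,
  "firing_floor": 1e-09,
  "fallback": 0.0,
  "fou_widths": {"f1": 0.25, "f2": 0.05, "f3": 0.0},
  "membership_functions": {
    "f1": {
      "L": [null, null, 0.55, 0.9],
      "M": [0.75, 0.9, 1.2, 1.55],
      "H": [1.05, 1.55, null, null]
    },
    "f2": {
      "L": [null, null, 0.55, 0.9],
      "M": [0.75, 0.9, 1.2, 1.55],
      "H": [1.05, 1.55, null, null]
    },
    "f3": {
      "L": [null, null, 0.55, 0.9],
      "M": [0.75, 0.9, 1.2, 1.55],
      "H": [1.05, 1.55, null, null]
    }
  },
  "rules": [
    {"if": ["L", "L", "L"], "then": 1.0},
    {"if": ["M", "M", "M"], "then": 0.0},
    {"if": ["H", "H", "H"], "then": 1.0}
  ]
}
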