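{
  "1": {
    "label": "reward_frequency",
    "components": [
      {"reward": {"p": [0.25, 0.75], "amount": [50, 50], "variable": false},
       "penalty": {"p": [0.50, 0.50], "amount": [30, 30], "variable": false}},
      {"reward": {"p": [0.35, 0.65], "amount": [50, 50], "variable": false},
       "penalty": {"p": [0.50, 0.50], "amount": [30, 30], "variable": false}},
      {"reward": {"p": [0.65, 0.35], "amount": [50, 50], "variable": false},
       "penalty": {"p": [0.50, 0.50], "amount": [30, 30], "variable": false}},
      {"reward": {"p": [0.75, 0.25], "amount": [50, 50], "variable": false},
       "penalty": {"p": [0.50, 0.50], "amount": [30, 30], "variable": false}}
    ]
  },
  "2": {
    "label": "reward_magnitude",
    "components": [
      {"reward": {"p": [0.50, 0.50], "amount": [25, 75], "variable": true},
       "penalty": {"p": [0.50, 0.50], "amount": [30, 30], "variable": false}},
      {"reward": {"p": [0.50, 0.50], "amount": [35, 65], "variable": true},
       "penalty": {"p": [0.50, 0.50], "amount": [30, 30], "variable": false}},
      {"reward": {"p": [0.50, 0.50], "amount": [65, 35], "variable": true},
       "penalty": {"p": [0.50, 0.50], "amount": [30, 30], "variable": false}},
      {"reward": {"p": [0.50, 0.50], "amount": [75, 25], "variable": true},
       "penalty": {"p": [0.50, 0.50], "amount": [30, 30], "variable": false}}
    ]
  },
  "3": {
    "label": "penalty_frequency",
    "components": [
      {"reward": {"p": [0.50, 0.50], "amount": [170, 170], "variable": false},
       "penalty": {"p": [0.75, 0.25], "amount": [50, 50], "variable": false}},
      {"reward": {"p": [0.50, 0.50], "amount": [170, 170], "variable": false},
       "penalty": {"p": [0.65, 0.35], "amount": [50, 50], "variable": false}},
      {"reward": {"p": [0.50, 0.50], "amount": [170, 170], "variable": false},
       "penalty": {"p": [0.35, 0.65], "amount": [50, 50], "variable": false}},
      {"reward": {"p": [0.50, 0.50], "amount": [170, 170], "variable": false},
       "penalty": {"p": [0.25, 0.75], "amount": [50, 50], "variable": false}}
    ]
  },
  "4": {
    "label": "penalty_magnitude",
    "components": [
      {"reward": {"p": [0.50, 0.50], "amount": [170, 170], "variable": false},
       "penalty": {"p": [0.50, 0.50], "amount": [75, 25], "variable": true}},
      {"reward": {"p": [0.50, 0.50], "amount": [170, 170], "variable": false},
       "penalty": {"p": [0.50, 0.50], "amount": [65, 35], "variable": true}},
      {"reward": {"p": [0.50, 0.50], "amount": [170, 170], "variable": false},
       "penalty": {"p": [0.50, 0.50], "amount": [35, 65], "variable": true}},
      {"reward": {"p": [0.50, 0.50], "amount": [170, 170], "variable": false},
       "penalty": {"p": [0.50, 0.50], "amount": [25, 75], "variable": true}}
    ]
  }
}
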