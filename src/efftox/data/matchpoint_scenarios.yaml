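# Six simulation scenarios for the Matchpoint design: assumed true
# efficacy/toxicity probabilities per dose and the correct final action.
scenarios:
  - label: "1: monotonic, dose 4 optimal"
    true_eff: [0.20, 0.30, 0.50, 0.60]
    true_tox: [0.03, 0.05, 0.10, 0.30]
    correct: 4
  - label: "2: monotonic, dose 2 optimal"
    true_eff: [0.40, 0.60, 0.75, 0.79]
    true_tox: [0.10, 0.25, 0.55, 0.60]
    correct: 2
  - label: "3: efficacy plateau, dose 3 optimal"
    true_eff: [0.25, 0.40, 0.60, 0.60]
    true_tox: [0.10, 0.20, 0.38, 0.42]
    correct: 3
  - label: "4: toxicity plateau, dose 4 optimal"
    true_eff: [0.50, 0.60, 0.70, 0.80]
    true_tox: [0.20, 0.20, 0.20, 0.20]
    correct: 4
  - label: "5: all doses inactive"
    true_eff: [0.05, 0.08, 0.20, 0.25]
    true_tox: [0.05, 0.08, 0.12, 0.14]
    correct: stop
  - label: "6: all doses too toxic and inactive"
    true_eff: [0.05, 0.08, 0.12, 0.25]
    true_tox: [0.60, 0.65, 0.70, 0.80]
    correct: stop
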