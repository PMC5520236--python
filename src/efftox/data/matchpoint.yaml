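# Matchpoint trial design: ponatinib + FLAG-IDA in blast-phase CML.
# Four daily-equivalent ponatinib doses; dose 1 (7.5 mg/day) is 15 mg
# every other day. Elicited prior event probabilities per dose, prior
# strength ESS = 1.3 pseudo-patients.
label: matchpoint
doses: [7.5, 15, 30, 45]
prior_eff: [0.2, 0.3, 0.5, 0.6]
prior_tox: [0.025, 0.05, 0.1, 0.25]
ess: 1.3
contour:
  pi1E: 0.40        # minimum efficacy probability at zero toxicity
  pi2T: 0.70        # maximum toxicity probability at certain efficacy
  hinge: [0.50, 0.40]  # interior equal-utility point; pins p (= 2.07)
admissibility:
  pi_E_min: 0.45
  pi_T_max: 0.40
  p_E: 0.03
  p_T: 0.05
cohort_size: 3
max_patients: 30
start_dose: 3
no_skip_escalation: true
no_skip_deescalation: true
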