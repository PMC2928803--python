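# Reduced yEGFP galactose-uptake expression model in S. cerevisiae:
# 8 irreversible reactions, 4 states, 8 kinetic parameters.  Promoter
# configurations are in pseudo-equilibrium, so transcription appears as a
# constitutive propensity with the induction condition (2% galactose,
# 40 ng/ml ATc) absorbed into kappa_R.  Reconstruction: yEGFP and TetR
# are modelled as two two-stage expression cascades (transcription, mRNA
# decay, per-mRNA translation, protein decay).  Time is dimensionless.
species: [R, P, Rt, Pt]
parameters:
- name: kappa_R
  bounds: [0.0, 5.0]
  true_value: 1.0
- name: kappa_P
  bounds: [0.0, 5.0]
  true_value: 1.0
- name: gamma_R
  bounds: [0.0, 10.0]
  true_value: 5.0
- name: gamma_P
  bounds: [0.0, 5.0]
  true_value: 0.0125
- name: kappa_Rt
  bounds: [0.0, 5.0]
  true_value: 0.417
- name: kappa_Pt
  bounds: [0.0, 5.0]
  true_value: 1.0
- name: gamma_Rt
  bounds: [0.0, 10.0]
  true_value: 3.0
- name: gamma_Pt
  bounds: [0.0, 5.0]
  true_value: 0.0125
reactions:
- name: transcription_G
  stoichiometry: {R: 1}
  propensity: {kind: mass_action, rate: [kappa_R]}
- name: rna_decay_G
  stoichiometry: {R: -1}
  propensity: {kind: mass_action, rate: [gamma_R], reactants: [R]}
- name: translation_G
  stoichiometry: {P: 1}
  propensity: {kind: mass_action, rate: [kappa_P], reactants: [R]}
- name: protein_decay_G
  stoichiometry: {P: -1}
  propensity: {kind: mass_action, rate: [gamma_P], reactants: [P]}
- name: transcription_T
  stoichiometry: {Rt: 1}
  propensity: {kind: mass_action, rate: [kappa_Rt]}
- name: rna_decay_T
  stoichiometry: {Rt: -1}
  propensity: {kind: mass_action, rate: [gamma_Rt], reactants: [Rt]}
- name: translation_T
  stoichiometry: {Pt: 1}
  propensity: {kind: mass_action, rate: [kappa_Pt], reactants: [Rt]}
- name: protein_decay_T
  stoichiometry: {Pt: -1}
  propensity: {kind: mass_action, rate: [gamma_Pt], reactants: [Pt]}
metadata:
  observables: [P, Pt]
  initial_state: {}
  time_unit: dimensionless
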