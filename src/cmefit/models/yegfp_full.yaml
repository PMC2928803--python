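# Complete yEGFP galactose-uptake expression model: 18 reactions,
# 9 states, 15 kinetic parameters.  Synthetic reconstruction from the
# published structure: five reversible promoter-configuration transitions
# (free PC1, intermediate PC2, pre-initiation PC3, repressed RC1/RC2;
# TetR binding at k3f scaled by the ATc-free active fraction alpha,
# unbinding at k3b) plus the 8 irreversible expression reactions of the
# reduced model, with transcription proceeding from PC3 only.
species: [PC1, PC2, PC3, RC1, RC2, R, P, Rt, Pt]
parameters:
- name: k1f
  bounds: [0.0, 5.0]
  true_value: 0.42
- name: k1b
  bounds: [0.0, 5.0]
  true_value: 0.2485
- name: k2f
  bounds: [0.0, 100.0]
  true_value: 50.0
- name: k2b
  bounds: [0.0, 20.0]
  true_value: 10.0
- name: k3f
  bounds: [0.0, 5.0]
  true_value: 3.032e-03
- name: k3b
  bounds: [0.0, 20.0]
  true_value: 10.0
- name: alpha
  bounds: [0.0, 5.0]
  true_value: 0.025
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
- name: pc1_to_pc2
  stoichiometry: {PC1: -1, PC2: 1}
  propensity: {kind: mass_action, rate: [k1f], reactants: [PC1]}
- name: pc2_to_pc1
  stoichiometry: {PC2: -1, PC1: 1}
  propensity: {kind: mass_action, rate: [k1b], reactants: [PC2]}
- name: pc2_to_pc3
  stoichiometry: {PC2: -1, PC3: 1}
  propensity: {kind: mass_action, rate: [k2f], reactants: [PC2]}
- name: pc3_to_pc2
  stoichiometry: {PC3: -1, PC2: 1}
  propensity: {kind: mass_action, rate: [k2b], reactants: [PC3]}
- name: repression_1
  stoichiometry: {PC1: -1, Pt: -1, RC1: 1}
  propensity: {kind: mass_action, rate: [k3f, alpha], reactants: [PC1, Pt]}
- name: derepression_1
  stoichiometry: {RC1: -1, PC1: 1, Pt: 1}
  propensity: {kind: mass_action, rate: [k3b], reactants: [RC1]}
- name: repression_2
  stoichiometry: {PC2: -1, Pt: -1, RC2: 1}
  propensity: {kind: mass_action, rate: [k3f, alpha], reactants: [PC2, Pt]}
- name: derepression_2
  stoichiometry: {RC2: -1, PC2: 1, Pt: 1}
  propensity: {kind: mass_action, rate: [k3b], reactants: [RC2]}
- name: rc1_to_rc2
  stoichiometry: {RC1: -1, RC2: 1}
  propensity: {kind: mass_action, rate: [k1f], reactants: [RC1]}
- name: rc2_to_rc1
  stoichiometry: {RC2: -1, RC1: 1}
  propensity: {kind: mass_action, rate: [k1b], reactants: [RC2]}
- name: transcription_G
  stoichiometry: {R: 1}
  propensity: {kind: mass_action, rate: [kappa_R], reactants: [PC3]}
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
  initial_state: {PC1: 1}
  time_unit: dimensionless
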