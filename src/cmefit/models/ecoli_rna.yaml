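# Single-gene mRNA dynamics in E. coli (MS2d-GFP reporter experiment).
# Reconstruction from the published model structure (3 reactions, 3 rate
# constants; silent and activated promoter forms): irreversible promoter
# activation, transcription from the active promoter, first-order mRNA
# decay.  Time unit: minutes.
species: [DNA_S, DNA_A, RNA]
parameters:
- name: k1
  bounds: [0.0, 5.0]
  true_value: 0.028
- name: k2
  bounds: [0.0, 5.0]
  true_value: 0.17
- name: k3
  bounds: [0.0, 5.0]
  true_value: 0.41
reactions:
- name: activation
  stoichiometry: {DNA_S: -1, DNA_A: 1}
  propensity: {kind: mass_action, rate: [k1], reactants: [DNA_S]}
- name: transcription
  stoichiometry: {RNA: 1}
  propensity: {kind: mass_action, rate: [k2], reactants: [DNA_A]}
- name: rna_decay
  stoichiometry: {RNA: -1}
  propensity: {kind: mass_action, rate: [k3], reactants: [RNA]}
metadata:
  observables: [RNA]
  initial_state: {DNA_S: 1}
  noise_variance: 0.25
  time_unit: min
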