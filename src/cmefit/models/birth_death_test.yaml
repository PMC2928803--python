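# Immigration-death test model: constant birth at rate k, first-order
# death at rate gamma per molecule.  Stationary law Poisson(k/gamma).
species: [X]
parameters:
- name: k
  bounds: [0.0, 10.0]
  true_value: 5.0
- name: gamma
  bounds: [0.0, 10.0]
  true_value: 1.0
reactions:
- name: birth
  stoichiometry: {X: 1}
  propensity: {kind: mass_action, rate: [k]}
- name: death
  stoichiometry: {X: -1}
  propensity: {kind: mass_action, rate: [gamma], reactants: [X]}
metadata:
  observables: [X]
  initial_state: {}
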