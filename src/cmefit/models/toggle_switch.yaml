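# Genetic toggle switch in E. coli (two mutually repressing
# repressor-promoter pairs, dimensionless Gardner form).  U is the
# LacI-side repressor, V the cI-side repressor whose promoter drives GFP.
# IPTG (6e-5 M) sequesters LacI, entering the V-synthesis propensity by
# rescaling the effective U level by (1 + [IPTG]/K)^eta.  Degradation
# rate constants are unity (not estimated).
species: [U, V]
parameters:
- name: alpha1
  bounds: [0.0, 200.0]
  true_value: 156.25
- name: alpha2
  bounds: [0.0, 20.0]
  true_value: 15.6
- name: beta
  bounds: [0.0, 10.0]
  true_value: 2.5
- name: gamma
  bounds: [0.0, 10.0]
  true_value: 1.0
- name: eta
  bounds: [0.0, 10.0]
  true_value: 2.0015
- name: K
  bounds: [0.0, 1.0]
  true_value: 6.0e-05
reactions:
- name: synthesis_U
  stoichiometry: {U: 1}
  propensity: {kind: hill, numerator: alpha1, regulator: V, exponent: beta}
- name: degradation_U
  stoichiometry: {U: -1}
  propensity: {kind: mass_action, rate: [], reactants: [U]}
- name: synthesis_V
  stoichiometry: {V: 1}
  propensity:
    kind: hill
    numerator: alpha2
    regulator: U
    exponent: gamma
    induction: {K: K, eta: eta, inducer_conc: 6.0e-05}
- name: degradation_V
  stoichiometry: {V: -1}
  propensity: {kind: mass_action, rate: [], reactants: [V]}
metadata:
  observables: [V]
  initial_state: {}
  iptg_conc_M: 6.0e-05
  time_unit: dimensionless
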