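# Methods

This note documents the models, estimation criteria, numerical
conventions and design choices behind `cmefit`, and what its tests do
and do not establish.

## Model class and simulation

A `ReactionNetwork` is a chemical-master-equation model: `N` species,
`M` reactions with integer stoichiometric changes `nu_j`, and
propensities `a_j(x, k)` such that `a_j dt` is the firing probability
of reaction `j` in `[t, t+dt)`. Propensities are mass-action (with an
optional fixed numeric prefactor and products of named constants),
repressive Hill terms `A / (1 + (x/s)^h)` (with an optional
inducer-sequestration scale `s = (1 + [I]/K)^eta`), or arbitrary
arithmetic formulas parsed by a whitelisting AST parser — no code
execution from model files.

Simulation is Gillespie's direct method, exact for the CME: waiting
times are exponential with rate `a0 = sum_j a_j` and the firing index
is drawn proportionally to `a_j`. The state recorded at a sample time
is the state holding over the inter-event interval containing it
(right-continuous step convention); when `a0 = 0` the state freezes.
Networks built from mass-action/Hill propensities run in a compiled
numba kernel; expression-propensity networks use an equivalent Python
engine, which also serves as an independent implementation for
cross-checking the kernel distributionally in the tests.

Randomness is explicit everywhere. Ensembles draw one child of a
`numpy` `SeedSequence` per realization, so realization `i` of an
ensemble is exactly a single-trajectory simulation on child stream `i`,
the same seed reproduces an ensemble bit-for-bit, and different seeds
give statistically independent streams.

Measurement noise models fluorescence-normalization error:
`o = round(x + eps)`, `eps ~ N(0, sigma^2)` i.i.d., applied only to the
designated reporter species, with negative observed counts preserved
(hidden species such as promoter states are never noised — measurements
are of the reporter).

## Densities and finite-sampling weights

Distributions are histograms with adaptive integer binning: unit-width
bins spanning the sample range are merged — leftmost-first, each
undersized bin into its smaller-count neighbour, ties rightward — until
every bin holds at least `min_count = 10` samples (or one bin remains).
The rule balances binning bias against per-bin sampling noise; the
merge order makes the scheme deterministic and invariant to sample
permutation. Bins are half-open `[e_l, e_{l+1})` with the last bin
closed; the observed-count axis extends to negative integers when noise
produces them.

The sampling variance of a bin frequency is binomial, `p(1-p)/N`, and
identically `F(1-F)/N` for cumulative frequencies. The cumulative
coefficient of variation `sqrt((1-F)/(N F))` decreases in `F`, which is
why the CDF is better resolved than the PDF at equal sample size — the
root of the CDF criterion's robustness.

For sparse data (few replicates `m`) the empirical CDF is the
order-statistic plotting-position form `F_e(o_(l)) = (l - 0.5)/m`;
tied values keep consecutive positions (zero-width steps).

## Estimation criteria

All criteria compare the data with a model-side SSA ensemble of
`n_ssa` realizations carrying the dataset's noise model, and all sum
over observed species and sample times.

* **ML**: `sum_ij -log P(o_ij, t_i)`, with the model PDF binned on the
  simulation. Observations in a zero-probability or out-of-support bin
  contribute the floor `1/(10 n_ssa)` instead of 0 — the objective
  stays finite while unexplained observations are penalized heavily.
  The floor choice is a convention; any sufficiently small value only
  rescales the penalty.
* **DFD-PDF / DFD-CDF (dense)**: weighted squared distances with the
  binning referenced to the experimental data, weights from the data
  side with the data's sample size. The last bin per timepoint is
  excluded: normalization makes it linearly dependent on the rest.
  Bins with zero variance contribute nothing when the densities agree
  there and otherwise use the floor variance `1/(4 N^2)` (order of the
  smallest nonzero value of `p(1-p)/N` squared in `1/N`).
* **DFD-CDF (sparse)**: the model CDF is binned on the SSA
  realizations, linearly interpolated at the sorted data values
  (anchored at zero on the lower support edge, saturating at 1), and
  compared to the plotting positions with weights `F_e(1-F_e)/m`. All
  `m` order statistics enter: the dense-mode last-bin degeneracy does
  not arise since `F_e(m) < 1`.
* **Max variants**: per-timepoint maximum of `|difference|` over the
  binomial standard deviation, summed over times.

DFD-PDF (and the max variants) refuse datasets below a population
threshold (default 1000 replicates) where data histograms are
unreliable, unless explicitly overridden; DFD-CDF switches to sparse
mode there.

## Optimization

The objective surfaces are stochastic and non-differentiable, so the
minimizer is Differential Evolution, strategy rand/1/bin: mutant
`v = x_r1 + F (x_r2 - x_r3)`, binomial crossover with one guaranteed
coordinate, greedy selection, out-of-bounds coordinates reflected back
into the box. Defaults `F = 0.5`, `CR = 0.9` (the canonical
recommendations) and population `10 x` the number of free parameters;
termination is a fixed generation count, with an optional
population-spread early stop (off by default).

By default the SSA sub-streams and noise draws inside the objective are
frozen for a whole run (common random numbers), making the objective a
deterministic function of the parameters: selection compares like with
like, the best-so-far history is exactly monotone, and a run replays
bit-for-bit from its configuration. A flag redraws streams per
evaluation instead (used by the roughness diagnostic below).

## Case-study models

The shipped models are reconstructions: the original supplementary
tables with the exact propensity assignments were not available, so the
networks were rebuilt from the published structure counts, parameter
names/bounds/true values, and the behaviour of the underlying
experiments. Concretely:

* **ecoli_rna** (3 reactions, 3 constants, minutes): irreversible
  promoter activation `DNA_S -> DNA_A` (k1 = 0.028), transcription
  `DNA_A -> DNA_A + RNA` (k2 = 0.17), mRNA decay (k3 = 0.41). This
  assignment reproduces the published qualitative behaviour — the mean
  rises and plateaus on the `1/k1 ~ 36 min` timescale within the
  75-minute horizon — and implies an mRNA half-life of ~1.7 min. An
  alternative reading (reversible switching, no decay) grows linearly
  without plateau and was rejected. Protocol: every 0.5 min to 75 min
  (151 timepoints), reporter mRNA observed with `N(0, 0.25)` rounding
  noise. Note the identifiability structure: per-timepoint marginals
  pin `k1` and the ratio `k2/k3` strongly but the scale of `(k2, k3)`
  only weakly (a long flat ridge); short optimizer runs recover `k1`
  well while `(k2, k3)` may sit high on the ridge.
* **yegfp_reduced** (8 irreversible reactions, 4 states, 8 constants,
  dimensionless time): promoter configurations in pseudo-equilibrium,
  leaving two two-stage expression cascades (transcription, mRNA decay,
  per-mRNA translation, protein decay) for yEGFP and TetR, with the
  induction condition absorbed into the transcription constants.
  Protocol: both proteins observed every 5 units to 50, no added noise.
* **yegfp_full** (18 reactions, 9 states, 15 constants): five
  reversible promoter transitions (free/intermediate/pre-initiation
  and two TetR-repressed configurations, binding scaled by an
  ATc-active fraction `alpha`) plus the 8 expression reactions, with
  transcription from the pre-initiation state. This network is a
  labelled synthetic reconstruction — useful for scalability
  experiments, not a literal replica.
* **toggle_switch** (4 reactions, 6 estimated constants,
  dimensionless): Gardner-form mutual repression with unit degradation
  rates. IPTG (6e-5 M) sequesters the LacI-side repressor, rescaling
  its effective level by `(1 + [I]/K)^eta` inside the cI-side Hill
  term. The observed species is the cI/GFP-side repressor; at the true
  constants its endpoint marginal is clearly bimodal (latched
  subpopulations). Protocol default: one flow-cytometry-like endpoint
  snapshot at t = 50 (several relaxation times), configurable to a
  time series.

## Reduced problem sizes

The published estimation runs used `10^4` SSA realizations per
objective evaluation and thousands of DE generations (hours to days of
compute). The package's tests and acceptance script use deliberately
reduced scales, chosen as the smallest budgets at which each scientific
claim is decidable:

* mRNA-model recovery: m = 10^4 data, n_ssa = 1000, NP = 15, G = 120 —
  recovers k1 to ~5–10%.
* Convergence-speed ordering (CDF before PDF before ML): run on the
  identifiable (k1, k3) subproblem with k2 held at truth, five
  optimizer seeds, a deliberately tight budget (G = 25, NP = 15,
  n_ssa = 400). The budget must sit where the steepest criterion has
  converged and the flatter ones have not; on the full 3-parameter
  problem at short budgets the error medians measure ridge position
  rather than convergence and the comparison is uninformative.
* yEGFP and toggle recovery: conditional two-parameter estimations
  (decay constants gamma_R, gamma_P; toggle alpha2, gamma) with the
  remaining constants fixed at truth — full 8/6-parameter runs at
  published scale are outside any test budget.
* Landscape diagnostics: 7x7 grids over (k2, k3) in [0.1, 1] for the
  curvature comparison (normalized second differences at the grid
  minimum); a 6x6 local grid (±10% around truth) for the
  finite-sampling roughness, measured as the RMS residual of a local
  quadratic fit relative to the spread of the fitted trend, with
  independent streams per node. Adjacent-difference roughness of the
  min-normalized surface is also provided but conflates steepness with
  noise (surfaces at larger n_ssa are steeper after normalization),
  so the detrended noise-to-signal ratio is the diagnostic quantity.

## What the synthetic data do and do not show

The generators emulate the in-silico protocols of the case studies:
exact-SSA replicates with i.i.d. rounded-Gaussian reporter noise and
fixed sampling grids. Passing recovery tests shows the estimation
machinery is correct and informative under the assumed model class.
Real datasets additionally contain cell-to-cell extrinsic variability,
autofluorescence background, non-Gaussian and count-dependent
measurement error, cell-cycle and division effects, and model
misspecification — none of which are represented; estimator accuracy
on real data will be correspondingly worse. The recovery experiments
also condition on the correct network topology and (for case studies
2–3) on a subset of the constants.

## Known limitations

* Exact SSA only — no tau-leaping or diffusion approximations, so
  stiff or high-copy-number systems are expensive.
* One CPU: the DE loop evaluates candidates serially (a process-pool
  hook would be the natural extension).
* Single-species histograms: multivariate dependence between observed
  species is not used (objectives sum over species marginals).
* Weak identifiability is reported, not resolved: no profile
  likelihoods or experiment-design tooling.
* No gradient-based refinement after DE; the stochastic surface makes
  gradients meaningless at realistic `n_ssa`.
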