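# Methods

This note documents the model the engine implements, the synthetic tasks and
study conditions, the numerical choices, and known limitations.  Nothing here
reports a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Generative model and inference

Each hierarchical level is a categorical hidden-Markov model: a likelihood
`P(o|s)` stored as an outcome × state column-stochastic matrix (optionally
with Dirichlet concentration counts and a boolean `frozen_mask`), per-action
transition kernels indexed `[action, next, current]`, a prior over initial
states, unnormalised log-preferences over outcomes, a context × policy habit
potential `E`, a discretised prior over the precision `β`, and a set of
fixed-length policies.

State inference is **exact**: the policy-conditioned posterior over the
state trajectory is computed by scaled forward–backward over the chain
selected by the policy's actions, and the variational free energy of a
policy therefore coincides with its log marginal likelihood,
`F(π) = ln P(o_<|π)`.  No variational approximation is used anywhere; the
acceptance checks verify `F` against brute-force trajectory enumeration to
1e-10.

Two belief streams coexist in the perception–action loop, deliberately.
Policy scoring uses each policy's *own* action sequence, so that `F` carries
behavioural momentum (a policy inconsistent with the observed history is
penalised).  Dirichlet learning instead conditions on the actions actually
executed, which is the correct credit assignment for plasticity: the count
increment is `rate · P(o) · Q(s)` with `Q(s)` the filtered belief under the
executed actions.  Learning uses the belief at the newly observed timestep;
the learning rate defaults to 1.0 (one effective pseudo-observation per
observation).  Whether the smoothed or filtered belief is used is switchable
at the `update_dirichlet` call site; the loop uses the filtered belief at
the current time, which equals the smoothed belief there.

## Policy objectives

All objective terms are in nats and, for multi-step policies, per-timestep
contributions are summed over the remaining horizon (additivity is a
convention, not forced by the framework).  The sign convention throughout:
**G is maximised**.

- `mutual_information` offers the three standard factorisations (joint-KL,
  expected posterior divergence, entropy difference); they agree to 1e-10
  and any of them may be used.
- `utility` is the expected log of the *normalised* preference distribution.
  Preferences are stored unnormalised because only their differences matter;
  normalising on demand makes `value = −KL[P(o|π) ‖ P(o|C)] ≤ 0` exact and
  gives the decomposition `G = value − ambiguity`.
- `parameter_info_gain` (novelty) is the expected KL between post-update and
  pre-update Dirichlet likelihood beliefs, averaged under the policy's
  predictive joint `P(s|π)P(o|s)` and computed with the closed-form
  Dirichlet KL.  Entries under `frozen_mask` contribute exactly zero: a
  frozen count cannot change, so observing it teaches nothing.  This is the
  canonical Bayesian reading of "expected information gain about
  parameters"; it enters `G` additively.

## Precision-weighted policy posterior

The habit potential is combined with the free energies per Eq.-style
weighting: for each gridpoint `β` and context state, the softmax of
`β·E + F + G` is taken *first* and then averaged under the context belief
(the expectation sits outside the softmax); the marginal policy posterior
averages the conditionals under the precision belief.  With a flat habit or
no context this collapses exactly to `softmax(F + G)`.  The policy *prior*
uses `G` alone (`softmax(G)`); `F` enters only the posterior.

The precision posterior is `Q(β) = E_Q(π)[softmax_β(ln Q(π|β) + ln P(β))]`,
evaluated exactly on the grid, and the two updates are alternated
(`iterate_policy_precision`, max 16 iterations, tolerance 1e-6, damping 0.5
on the precision update) until the L1 change of both weight vectors falls
below tolerance.

**An exactness identity worth knowing.**  When the policy weights fed into
the precision update are themselves the precision-mixture of the same
conditionals — which is what the loop produces — the marginal precision
posterior reproduces its prior *identically*:
`Σ_π Q(π) · P(β)Q(π|β)/Z_π = P(β) Σ_π Q(π|β) = P(β)`.  The precision
influences data only through policies, and marginalising back out undoes
the conditioning.  Consequently the converged `E[β]` equals the prior mean
(the reciprocity experiments report `posterior ≤ prior`, satisfied with
equality), and the directional claim — confidence in the free-energy
potentials lowers the precision of the habit prior — lives at the level of
the *conditionals* `Q(β|π)`: the policy favoured by `F + G` against the
habit carries a `Q(β|π)` tilted toward low `β`, and the habit-favoured
policy toward high `β`.  The test suite checks both facts.  Simulations
therefore log a constant `E[β]` unless the precision is clamped by a
lesion; `1/E[β]` is reported as `precision_inverse` (a naming convention
for the dopamine analogy, nothing more).

The β grid defaults to 32 log-spaced points on [0.1, 10] carrying a
discretised Gamma(shape 4, rate 4) prior (mode near β = 1, i.e. habits and
free energies initially comparable).  The Gamma family is a choice — the
framework does not fix `P(β)` — and both grid and weights are exposed in
the model config.

## Hierarchy

Exactly two levels are implemented; one level-2 timestep spans one full
level-1 trial.  The descending message projects the level-2 state belief
through a `context_map` onto the level-1 habit-context axis and may blend
per-level-2-state preference vectors (log-preferences mix linearly, i.e.
geometrically on the probability scale) and initial-state priors.  The
ascending message is the policy-averaged final smoothed state belief,
entering level 2 as *soft evidence* (belief-weighted likelihood,
`L(s₂) = Σ_o m(o) P(o|s₂)`); a hard mode (argmax outcome, lowest index on
ties) is available.  Soft evidence was chosen because the framework gives no
explicit level-2 likelihood for "states of the level below"; with a
habit-neutral deep model and identity link the hierarchical agent reproduces
the flat agent exactly (tested to 1e-10).  Between trials the level-2 belief
is propagated through the level-2 transition kernel of its single policy.

## Lesions

- `likelihood_disconnection` sets `frozen_mask` on targeted likelihood
  entries.  Deliberately, this freezes *learning* (and hence novelty) but
  leaves perception through the existing mapping intact — a cut axon's
  efficacy can no longer change, but the framework does not claim perception
  through remaining structure is abolished.
- `efe_knockout` forces `G(π) = 0` for targeted policies — the
  uninformative potential under a softmax — rather than −∞, modelling
  degraded (not abolished) policy differentiation.  By default all policies
  are targeted; a mask restricts it.  `onset` is a trial index;
  `onset_step` additionally delays the knockout to a timestep within each
  affected trial, which is what the perseveration experiment needs (the
  behaviour must first be initiated intact).
- `precision_clamp` replaces the β grid with a single value.

Phenotypes are operationalised as: laterality index (left − right saccade
share, in [−1, 1]), repeat rate (share of trials continuing an initiated
policy past the required count), and action rate (share of non-null
actions).  Comparisons are seed-paired — intact and lesioned runs share
environment randomness through per-trial counter-based substreams
(`[seed, trial, 0]` for the environment, `[seed, trial, 1]` for the agent) —
with 1000-resample bootstrap percentile intervals on the paired differences.

## Synthetic tasks and study conditions

The tasks are the engine's study conditions; their defaults were fixed once,
on mechanistic grounds, and define what the experiments mean.

**Saccade task** (4 locations, 3 categories, `counts_scale` 0.5, plus a
known start-fixation state).  Location likelihood columns start as flat
Dirichlet counts at 0.5 — a weak, symmetric state of ignorance under which a
single observation still changes beliefs appreciably (novelty ≈ 0.4 nats per
unvisited location) — so with flat preferences exploration is purely
novelty-driven.  Policies are single-step saccades; with deterministic gaze
transitions the predictive state is a point mass, so state information gain
is zero by construction and novelty is the only asymmetry — the cleanest
staging of the neglect argument.  The environment draws one fixed random
category per location per seed.

**Repetition task** (`n_required` 3, horizon 8, preference strength 3 nats,
observation noise 0.02).  States and outcomes count completed repetitions;
the policy family is "repeat k then stop" (k = 0..8).  Preferences put 3
nats on observing exactly `n_required` repetitions — enough for a near-
deterministic intact stop (utility gaps of several nats between adjacent
policies) without extreme potentials.  The horizon extends well past the
required count because perseveration can only express itself if the trial
leaves room for it.  The slight observation noise keeps free energies finite
for policies contradicted by the history.

**Context-choice task** (`p_cue_valid` 0.9 default, `reward_pref` 4 nats).
Level-2 states are two contexts, redrawn each trial (the level-2 transition
is maximally mixing); a level-1 trial is cue → delay → choice, with "juice"
emitted only after the context-matching choice.  Interoceptive (juice) and
exteroceptive (cue) outcomes are separate indices of a single outcome
modality.  4 nats of juice preference yields a ≈ 0.98 softmax choice
probability under a certain context belief — strong motivation, not a hard
constraint.

**What the generators do not emulate**: real saccade kinematics or visual
rendering, graded partial lesions, multi-modality or factorised state
spaces, reaction times, and any within-trial change of the true context.
Passing phenotype tests therefore demonstrates the *direction* of each
predicted behavioural effect under clean conditions, not quantitative
magnitudes in real subjects.

**Study sizes.**  The algebraic checks use 200 random models (dimensions
2–6) and the property sweep 1000 instances.  The neglect study runs 100
seed pairs × 40 trials with deterministic (argmax) action selection: the
claim under test is which saccade maximises expected information gain, and
argmax makes the per-seed sign of the laterality difference reflect that
ordering rather than binomial sampling noise (posterior sampling remains the
default mode elsewhere and is what the uniform-exploration and
sampling-frequency tests use).  The perseveration study runs 100 seed pairs
× 20 trials with sampled actions; the learning study 20 seeds × 200 trials
with the curve summarised in 8 trial blocks.

## Numerical choices

- Probabilities are floored at 1e-16 before any logarithm; the equations
  assume strictly positive densities.  Observations that are impossible
  under a policy yield a large negative, finite `F` rather than −∞.
- Softmax subtracts the maximum before exponentiating; shift invariance and
  normalisation hold to 1e-12 for potentials up to magnitude 700.
- Nonnegative quantities (mutual information, ambiguity, novelty) are
  clipped at zero; the clip only ever acts at the 1e-15 rounding scale.
- Ties in argmax action selection and in hard ascending messages resolve to
  the lowest index.
- Degenerate filtering steps (prior × likelihood identically zero) fall
  back to a uniform belief and charge `ln(1e-16)` to the evidence.
- All randomness flows through `numpy.random.Generator` seeded from
  explicit integer lists; equal (config, seed) runs are byte-identical.

## Limitations

- Single state factor and single outcome modality per level; two levels
  only.
- The precision prior is not conditioned on higher-level states: the
  framework notes the coupling but leaves its functional form unspecified,
  and guessing one was deliberately avoided.
- The marginal precision posterior is prior-invariant under exact grid
  inference (see above); dopamine-like *dynamics* of `E[β]` would require a
  different (e.g. variational Gamma) precision update, which is outside
  this package's exact-inference remit.
- The expected free energy is evaluated under the current likelihood matrix;
  within-rollout parameter updates (non-stationary novelty across a long
  horizon) are ignored, as is standard.
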