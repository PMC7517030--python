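# planinf

A discrete-state **planning-as-inference** agent engine for computational
neuroscience and behavioural modelling.  Agents hold a categorical generative
model of their world; deciding what to do next is cast as inferring a
posterior over *policies* (fixed-length action sequences), and the
ingredients of that posterior each carry a behavioural and neurobiological
interpretation.  A perturbation toolkit lets you lesion the message passing
in silico and measure the predicted phenotypes — hemispatial neglect,
perseveration, and akinesia/impulsivity — on matched synthetic tasks.

## The model

Perception is exact Bayes on a hidden-Markov chain: states `s` generate
outcomes `o` through a likelihood `P(o|s)` (optionally parameterised by
Dirichlet counts, so it can be learned), and policies `π` select transition
kernels `P(s'|s, a)`.  Three potentials score each policy:

- **Expected free energy** `G(π)` — *maximised* in this package's sign
  convention:

  ```
  G(π) = H[P(o|π)] + E_{P(o|π)}[ln P(o|C)] − E_{P(s|π)}[H[P(o|s)]]
       = information gain + utility            (exploration + exploitation)
       = value − ambiguity
  ```

  where `C` is a preference distribution over outcomes and
  `value = −KL[P(o|π) ‖ P(o|C)]` is the KL-control value.  When the
  likelihood carries Dirichlet counts a *novelty* term — the expected KL
  between post- and pre-update parameter beliefs — is added, so unexplored
  observations attract behaviour.  (Note: much published work minimises
  `−G`; all quantities here are in nats.)

- **Variational free energy** `F(π) = ln P(o_< | π)` — the evidence past
  observations lend each policy.  Because inference is exact, this is the
  log marginal likelihood.  It gives behaviour momentum: a policy already
  under way accumulates evidence for its own continuation.

- **Habit potential** `E(π, context)` — an empirical prior supplied by a
  slower hierarchical level, weighted by a **precision** (inverse
  temperature) `β` with a discretised prior.  The posterior over policies is

  ```
  Q(π|β) = E_Q(context)[ softmax_π( β·E + F + G ) ],   Q(π) = E_Q(β)[Q(π|β)]
  ```

  with the precision itself inferred reciprocally,
  `Q(β) = E_Q(π)[ softmax_β( ln Q(π|β) + ln P(β) ) ]`.  Logs report
  `1/E[β]` as `precision_inverse` (the dopamine analogue of the
  neurobiological reading).

Lesions target each potential: freezing Dirichlet counts abolishes novelty
(neglect); forcing `G` to zero leaves `F` in charge (perseveration);
clamping `β` high or low trades habit dominance against free-energy
dominance (akinesia vs impulsivity).

## Worked example: an in-silico neglect experiment

Four gaze locations (two "left", two "right") hold unknown visual
categories; with flat preferences, saccades are driven purely by novelty.
Freezing the left locations' likelihood counts — the operational reading of
a right-hemisphere disconnection — makes leftward saccades uninformative:

```python
import planinf as pi
from planinf.tasks import left_hemifield_mask

model, env = pi.make_saccade_task(n_locations=4, n_categories=3,
                                  counts_scale=0.5, seed=0)
lesion = pi.LesionSpec(kind="likelihood_disconnection",
                       target_mask=left_hemifield_mask(model, 4))

intact = pi.run_trials(model, env, n_trials=40, seed=0, mode="argmax")
model2, env2 = pi.make_saccade_task(seed=0)   # same scene, same seed
lesioned = pi.run_trials(model2, env2, n_trials=40, seed=0,
                         lesion=lesion, mode="argmax")

cmp = pi.phenotype_compare(intact, lesioned, seed=0)
print("intact   laterality:", cmp.intact.laterality_index)
print("lesioned laterality:", cmp.lesioned.laterality_index)
```

prints

```
intact   laterality: 0.0
lesioned laterality: -1.0
```

The laterality index is (left − right) saccade share in [−1, 1]: the intact
agent explores both hemifields evenly (0.0), while the lesioned agent, whose
left-hemifield novelty is exactly zero, saccades only rightward (−1.0).  The
seed-paired bootstrap difference is −1.000 with 95% interval [−1.300,
−0.700], excluding zero.  On the first trial, before anything is learned,
every saccade carries the same potential `G ≈ −0.954` and the policy
posterior is uniform (0.25 each); the asymmetry is created entirely by the
lesion.

The same machinery is scriptable from the shell:

```bash
planinf run --task saccade --trials 40 --seed 0 --out runs/intact
planinf run --task saccade --trials 40 --seed 0 --lesion lesion.yaml --out runs/lesioned
planinf phenotype --intact runs/intact --lesioned runs/lesioned --out phenotype.csv
planinf validate --model model.json
```

Each run writes `trials.csv` (one row per timestep: observation, action,
state beliefs, per-policy `E`/`F`/`G`, policy posterior, `E[β]`, `1/E[β]`)
and a `manifest.json` with the config hash, seed and library versions; equal
(config, seed) pairs give byte-identical CSVs.

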