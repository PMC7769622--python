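# gazemix

A generative model of saccadic scan paths in natural scene viewing, with
fully Bayesian parameter inference and likelihood-based evaluation.

When people look at an image, every saccade is a decision: inspect the
neighbourhood of the current fixation further (**local attention**) or
jump to another interesting region of the scene (**global attention**)?
`gazemix` implements a two-state mixture model of this decision on top of
a static saliency map `s(z)` (the empirical fixation density of the
image).  Writing a scan path as Z = {z₁, z₂, …, z_T}, the model is a
second-order Markov process

```
p(Z | Θ) = s(z₁) s(z₂) ∏_{t≥3} [ ρ_t p_local(z_t | z_{t−1}) + (1 − ρ_t) p_global(z_t | z_{t−1}) ]
```

with

- `p_local(z | z_prev) ∝ n(z; z_prev, ε)` — a diagonal Gaussian around the
  current fixation (short saccades),
- `p_global(z | z_prev) ∝ max(s(z) n(z; z_prev, ξ) − n(z; z_prev, ε), 0)` —
  the saliency map modulated by a broad Gaussian, with the local kernel
  subtracted and clamped at zero so that global saccades have a minimum
  length (a repulsion zone), and
- `ρ_t = σ(b (s(z_{t−1}) / s(z_{t−2}) − s°))` — a logistic gate on the
  saliency ratio of the two most recent fixations: landing on a more
  salient spot than before favours staying local.

The parameters Θ = {ε_x, ε_y, ξ_x, ξ_y, b, s°} (with ξ > ε per axis) are
inferred by a Gibbs sampler that augments the likelihood with per-saccade
Bernoulli mode indicators γ_t and Pólya-Gamma auxiliaries w_t, giving
exact Gaussian full conditionals for (b, s°), a conjugate update for the
mixture tags, and a Hamiltonian Monte Carlo step for the covariance
scales (Inverse-Gamma priors).  Simplified competitor variants —
`local_choice` (gate on the raw saliency value), `fixed_choice` (constant
gate), `local_saliency` (single mode), `saliency_baseline` (i.i.d.
draws from the map) — share the machinery.  Fitted models are compared by
AUC-Borji, normalized scanpath saliency (NSS), and information gain (IG,
bit/fix) under by-image cross-validation, and by saccade statistics
(amplitude densities, lag-1 amplitude anti-correlation, direction
distributions).

## Worked example

Simulate one observer from known parameters, fit the model, and score it:

```python
from gazemix import (Hyperparams, LocalGlobalAttentionModel, ModelParams,
                     synthetic_dataset)

truth = ModelParams(eps_x=9, eps_y=9, xi_x=200, xi_y=200, b=3.0, s_o=1.0)
ds = synthetic_dataset(truth, n_subjects=1, n_images=12, n_fix=20,
                       shape=(48, 48), seed=7, px_per_degree=2.0)

# wide priors on the 48x48 grid scale (saccades of ~1-20 px)
hyper = Hyperparams(alpha_eps=1.5, beta_eps=30, alpha_xi=1.5, beta_xi=250)
model = LocalGlobalAttentionModel(hyper=hyper, n_iter=400, n_burn=150,
                                  n_chains=2, random_state=0)
model.fit(ds.table, ds.saliency_maps)
print({k: round(v, 2) for k, v in model.posterior_.posterior_mean().items()})
print("R-hat:", {k: round(v, 2) for k, v in model.rhat_.items()})
print("IG: %.2f bit/fix" % model.score(ds.table, ds.saliency_maps))
```

Output from this exact script:

```
{'eps_x': 8.9, 'eps_y': 8.35, 'xi_x': 314.64, 'xi_y': 245.4, 'b': 3.67, 's_o': 0.91}
R-hat: {'eps_x': 1.01, 'eps_y': 1.01, 'xi_x': 1.11, 'xi_y': 1.07, 'b': 1.0, 's_o': 1.0}
IG: 2.38 bit/fix
```

The local scale, gate slope and offset land close to the generating
values (local sd 3 px, slope 3, offset 1); the global covariance is the
least constrained quantity at this deliberately small example size (12
paths) and carries wide posterior uncertainty.  The fitted model
predicts fixations about 2.4 bits per fixation better than a
uniform-over-pixels baseline.  Larger cohorts — e.g. the recovery
protocol in `gazemix.protocols` (30 paths) — pin all six parameters; see
`docs/methods.md`.

A command-line layer wraps the same workflows:

```bash
gazemix simulate --config cfg.yaml --outdir out/sim
gazemix fit      --config cfg.yaml --outdir out/fit out/sim/fixations.csv out/sim/maps
gazemix evaluate --config cfg.yaml --outdir out/ev  out/fit/posterior_subject_0.csv \
                 out/sim/fixations.csv out/sim/maps
gazemix recover  --config cfg.yaml --outdir out/rec --n-starts 10
```

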