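# Methods

## Model

A scan path on one image is an ordered sequence of fixation locations
Z = {z₁, …, z_T} on an H×W pixel grid (0-based indices, x = column,
y = row).  The saliency map s(z) is a normalized non-negative raster —
in practice the kernel-density estimate of pooled fixation locations —
treated as static input.  Saccade generation is modeled as a
second-order Markov process: the first two fixations are drawn from
s(z), and each later fixation from a two-component mixture

    p(z_t | z_{t−1}, z_{t−2}) = ρ_t p_local(z_t) + (1 − ρ_t) p_global(z_t).

**Local mode.**  p_local ∝ n(z; z_{t−1}, diag(ε_x, ε_y)), a bivariate
Gaussian around the current fixation, renormalized within the image.

**Global mode.**  p_global ∝ max(s(z) n(z; z_{t−1}, diag(ξ_x, ξ_y)) −
n(z; z_{t−1}, diag(ε_x, ε_y)), 0).  The broad Gaussian prefers salient
regions near the current fixation; subtracting the local kernel and
clamping at zero carves a *repulsion zone* so global saccades have a
minimum length.  The model requires ξ > ε per axis.

**Gate.**  ρ_t = σ(f_t) with f_t = b (s(z_{t−1})/s(z_{t−2}) − s°): a
high saliency ratio (landing somewhere more salient than before) favours
the local mode.  The denominator value is floored at 1e-12 of the map
mass (the map sums to one) because empirical maps can underflow.  For
the first modeled saccade (t = 3) the ratio uses s(z₂)/s(z₁), the only
available history.

**Variants.**  `local_choice` replaces the ratio by the raw value
s(z_{t−1}); `fixed_choice` uses a constant gate ρ; `local_saliency`
drops the mixture and samples every fixation from s(z) n(z; z_{t−1}, ξ)
renormalized; `saliency_baseline` draws every fixation from s(z).

All Gaussians are evaluated un-truncated at pixel centers and the maps
renormalized within the image (equivalent to truncation followed by
renormalization); likelihood, simulation and inference all live on this
same discrete measure, with exact inverse-CDF categorical sampling and
no sub-pixel jitter.  Per-step probabilities are floored at 1e-300
before logs; a step probability of exactly zero (possible inside the
repulsion zone) is reported in a diagnostic mask.  A parameter setting
that clamps the global map to zero everywhere at an observed origin is
outside the model's support and raises an error (simulation) or carries
log-density −∞ (inference).

## Inference

The mixture is augmented with per-saccade Bernoulli indicators
γ_t ~ Bern(ρ_t) (γ = 1 → local) and Pólya-Gamma auxiliaries
w_t ~ PG(1, f_t), which make the logistic gate conditionally Gaussian in
(b, s°).  One Gibbs sweep updates:

1. **(w, b, s°)** — w_t ~ PG(1, f_t) at the current link; then exact
   Gaussian full conditionals, by completion of squares: with design
   value x_t = r_t − s° (r_t the saliency ratio), prec_b = 1/σ_b² +
   Σ w_t x_t², mean_b = prec_b⁻¹(μ_b/σ_b² + Σ(γ_t − ½)x_t); the s°
   conditional is the mirror image with coefficient −b and offset b r_t.
   Because b and s° are strongly coupled, this grid-free block is
   re-scanned 5× per sweep (`link_sweeps`).
2. **(ε, ξ) | γ** — one HMC transition in log-scale coordinates
   targeting Σ_{γ=1} log p_local + Σ_{γ=0} log p_global + Inverse-Gamma
   log-priors + Jacobian.  Gradients are analytic; the clamp boundary is
   measure-zero and treated as gradient 0.  ξ > ε and global-map
   validity at every observed origin are enforced by −∞ (rejection).
   Step size is dual-averaged to a 0.65 acceptance rate during burn-in;
   default 5 leapfrog steps.
3. **(ε, ξ) marginal moves** — a small number (default 3) of random-walk
   Metropolis proposals in log-scale targeting the *tag-marginalized*
   mixture posterior.  Together with the immediate re-draw of γ this is
   a collapsed-Gibbs block (the joint draw p(scales | −γ) p(γ | scales)),
   so the stationary distribution is unchanged.  It is essential in
   practice: the tag-conditional HMC step alone can trap a chain in a
   metastable configuration where, e.g., only the very shortest saccades
   are tagged local and ε collapses; the marginal moves compare such
   basins directly and escape them.
4. **γ | rest** — independent Bernoulli draws with posterior success
   probability ρ_t p_local / (ρ_t p_local + (1 − ρ_t) p_global).

`fixed_choice` replaces step 1 by a conjugate Beta update of ρ;
`local_saliency` keeps only the HMC update of ξ; the baseline has
nothing to infer.  With an empty dataset every conditional reverts to
its prior (b, s° and ρ drawn exactly; scales via HMC on the prior),
which is the basis of the prior-recovery null check.

**Pólya-Gamma sampling** uses the truncated sum-of-Gammas representation
(200 terms) plus the expected mass of the dropped tail; the first moment
is exact to ~1e-7 and the draws pass moment and total-variation checks
against the closed forms.

**Initialization** disperses chains by seed: ε from a fraction of the
median squared step, ξ above it, (b, s°) from their priors; the tags
start from an amplitude split (short half local) with clamp-zone
saccades forced local, and the scales are shrunk/widened until the
global map is valid.  Dispersed starts otherwise frequently begin
outside the support or in the all-local trap.

**Diagnostics**: split-chain R-hat per parameter (threshold 1.1,
flagged, mirroring the exclusion of non-converged fits), HMC acceptance
rates, and a marginal log-posterior trace (up to the constant initial-
fixation terms).

**Priors.**  Defaults are wide and set from known saccade-amplitude
ranges (~0.5–40 degrees; at the default 4 px/degree, variances from a
few to ~2.5e4 px²): ε ~ IG(2, 25), ξ ~ IG(2, 2500) per axis,
b ~ N(0, 5), s° ~ N(0, 5), ρ ~ Beta(1, 1).  A data-dependent helper
centres the s° prior on the mean observed design value.  b and s° are a
priori independent.  Hyperparameters are fixed, never inferred.

## Synthetic data

`synthetic_saliency` builds multi-modal maps: n well-separated random
anisotropic Gaussian bumps over a uniform floor.  `synthetic_dataset`
simulates one path per (subject, image) — mirroring one trial per image
— with default sizes emulating one observer's experiment (30 images,
~35 fixations ≈ 10 s at 3–4 saccades/s).  For fitting protocols the
maps carry a 0.2–0.3 uniform-floor mass: empirical fixation-density
maps are smooth KDEs with broad support, and this matters statistically
— on near-zero-floor spiky maps the global targets are dictated by the
spikes alone and ξ is essentially unidentified.  What the generator
does *not* emulate: saccadic momentum (direction persistence), the
vertical-direction preference, fixation durations, and any dynamics of
the saliency map; passing the recovery and comparison checks therefore
says nothing about those aspects of real gaze data.

## Validation protocols and problem sizes

All sizes below are package choices balancing statistical validity
against desk-scale runtimes; they are fixed in `gazemix.protocols`.

- **Parameter recovery**: truth ε = 9 px² (3 px sd), ξ = 200 px²
  (~14 px sd), b = 3, s° = 1 on 48×48 grids at 2 px/degree; one
  observer of 30 paths × 24 fixations (~660 modeled saccades); priors
  IG(1.5, 30), IG(1.5, 250), N(0, 5) — wide, modes away from the truth;
  3 dispersed chains × 600 iterations (250 burn-in).  Checked: every
  true value inside the central 90% credible interval in ≥ 4 of 5
  seeded replicates, R-hat < 1.1.  Smaller cohorts (~400 saccades) make
  this check invalid rather than merely noisier: the finite-sample
  displacement of the (b, s°) maximum-likelihood point is O(1/n) and
  rivals the posterior sd there (verified by direct MLE studies; the
  score at the truth is zero-mean, so generator and likelihood agree).
- **Prior recovery**: 5000 post-burn-in draws (thinned ×5) on an empty
  dataset, KS-tested against each prior.
- **Amplitude structure**: 20 cohorts × 12 paths × 20 fixations from
  the full model (ε = 4, ξ = 120): local-tagged amplitudes
  stochastically smaller (Mann–Whitney), negative mean lag-1 amplitude
  autocorrelation (sign test); the single-scale variant shows neither.
- **Model comparison**: full-model data for 2 subjects × 30 images ×
  12 fixations on 32×32 grids (ε = 4, ξ = 90); 5-fold by-image
  cross-validation, per-subject fits (1 chain × 160 iterations), test
  scored at the posterior mean.  Checked: full-model test IG beats
  every simplified variant and `local_saliency` ranks last in the
  majority of 5 seeded replicates.
- **Saliency recovery**: 1e5 baseline-sampled fixations, merged-cell
  chi-square GOF against the generating map.

## Evaluation conventions

Scoring conditions each step's prediction map on the *observed* history
(teacher forcing); the first two fixations are scored under p(z) = s(z)
(configurable).  AUC-Borji uses 10 uniform negatives per positive and
midrank tie handling (equal to exhaustive pair counting); NSS z-scores
with population (ddof 0) std and counts constant maps as 0; IG is
log₂ p(z_t) + log₂(H·W) averaged per fixation.  Directions use
atan2(dy, dx) on image coordinates wrapped to (−180°, 180°]; direction
histograms use 36 × 10° bins; amplitude autocorrelation is the standard
per-path sample ACF averaged over paths, excluding paths too short for
a lag.  Cross-validation splits by image (held-out images unseen), one
model per subject, seeded folds; parameter uncertainty bands use
posterior draws (default 50) per fold.

## Known limitations

- The model cannot capture saccadic momentum or vertical direction
  preferences (single elliptical kernel per mode); direction-change
  histograms only show the boundary-induced ±180° mass.
- Exact-grid likelihoods cost O(paths × pixels) per sweep; fits beyond
  ~10³ saccades on grids ≳ 128×128 need patience (the hot loops are
  numba-compiled, with equivalent numpy fallbacks).
- The 90%-coverage recovery check is statistically demanding: for an
  exactly calibrated posterior each parameter misses a 90% interval in
  10% of replicates, so occasional boundary misses are expected even
  when everything is correct.
- R-hat on short chains is itself noisy; the 1.1 threshold follows
  common practice.
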