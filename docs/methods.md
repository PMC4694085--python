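# Methods

## The mixture model of continuous color report

A test trial's signed color error `e ∈ (−180°, 180°]` (response − studied,
wrapped) is modelled as

```
p(e | ρ, κ) = ρ · vM(e; κ) + (1 − ρ) / 360,
vM(e; κ)   = exp(κ cos e) / (360 · I₀(κ))     [density per degree]
```

`ρ` is the probability that the memory trace is accessible; `κ` the von
Mises concentration of the retrieved trace.  Fidelity is reported as the
circular SD `σ = (180/π)·sqrt(−2 ln(I₁(κ)/I₀(κ)))`, converted draw-wise
from the κ posterior (never from a summarized κ).  The Bessel ratio is
computed with exponentially scaled Bessel functions, so the conversion is
stable to the cap κ = 500 (σ ≈ 2.6°), which is also the cap used when
inverting σ → κ near σ → 0; κ = 0 maps to a documented +∞ sentinel.

### Hierarchy

With conditions `c ∈ {R, F}` and participants `p`:

```
logit ρ_cp = a_c + u_p,        u_p ~ Normal(0, s_u)
log   κ_cp = g_c + v_p,        v_p ~ Normal(0, s_v)
```

Random intercepts are shared across conditions (no random slopes; a
deliberate simplification, as condition-specific participant slopes are
weakly identified at 60 trials per cell).  The **variable-precision**
variant draws each trial's concentration as
`log κ_t ~ Normal(log κ_cp, τ)` (log-normal precision); the trial-level κ
is integrated out of the likelihood by Gauss–Hermite quadrature (11
nodes by default).  `τ = 0` recovers the fixed-precision model, so the
two variants are nested.

### Priors

Normal(0, 1.5) on the `a_c`; Normal(log 10, 1) on the `g_c`;
half-Normal(0, 0.5) on `s_u`, `s_v`, and `τ`.  These are weakly
informative, mildly skeptical defaults chosen once; every scale is a
constructor argument.  For the regression models: Normal(0, 2.5) on fixed
effects and half-Normal(0, 1) on SDs, both multiplied by the response SD
for Gaussian responses so the scales refer to standardized effects
(responses are left on their natural scale to keep printed coefficients
interpretable).  When a Gaussian response is exactly constant the prior
scale falls back to max(1, mean |y|).

### Inference

Participant random effects are marginalized on a tensor-product
Gauss–Hermite grid (15 × 15 nodes by default), leaving a 6–7 dimensional
group-level posterior.  That posterior is sampled with the
affine-invariant ensemble sampler (emcee): two independently seeded
ensembles of 16 walkers, default 1500 steps each with the first half
discarded as warmup, giving ≥ 20 000 retained draws.  Split R̂ (each
ensemble one chain, walkers pooled in step order so the split still
contrasts early vs late draws) and bulk ESS are computed with arviz;
R̂ ≥ 1.01 raises a warning but results are still returned.  Starting
values come from a collapsed (non-hierarchical) EM fit of the mixture,
which also serves as an independent cross-check in the test suite
(closed-form E-step; M-step by Bessel-ratio inversion).

The mixture likelihood is evaluated on a 1° error grid: errors are
rounded to the nearest degree, the 360-bin log-density table is computed
per parameter vector, and per-participant log-likelihood sums reduce to a
single matrix product with the participant × bin count matrix.  The ≤ 0.5°
rounding is negligible against σ ≥ 25°, and makes an E4-scale
variable-precision fit run in ~2–3 minutes on one CPU.  A density floor of
1e−300 keeps the log finite when ρ → 1 and the memory component
underflows on the far side of the wheel; log-SD parameters are bounded at
|log s| ≤ 8–25 (model-dependent) to stop degenerate zero-variance spikes
from running away.

### Pointwise log-likelihoods, WAIC, PSIS-LOO

For model comparison the trial-level *conditional* log-likelihood (given
participant effects) is used.  For each retained draw, participant
effects are sampled from their conditional posterior on the quadrature
grid, and each trial's mixture log density is evaluated at its error
(marginal over trial-level κ in the variable variant).  WAIC follows the
standard pointwise formulas with log-sum-exp stabilization; PSIS-LOO fits
a generalized Pareto (Zhang–Stephens profile posterior) to the largest
`ceil(min(0.2·S, 3·√S))` importance ratios of each trial, replaces them
with fitted quantiles, truncates at the maximum, and reports the tail
shape k̂ per trial (k̂ > 0.7 flags unreliable trials; a tail shorter than
5 points falls back to truncated importance sampling with a warning).
Comparisons are reported on the elpd scale with `delta = fixed − variable`,
so a negative delta favors the variable-precision model; the equivalent
deviance-scale difference is −2·delta.

## Regression models

* **Recognition** — multilevel logistic regression of a binary response
  (old/new; remember/not; know/no on the subset without a "remember"
  response) on item-type dummies with the foil (or first listed) level as
  intercept and participant random intercepts.  The binomial likelihood is
  collapsed to per-participant × condition counts and the random intercept
  integrated by 21-node Gauss–Hermite quadrature.  Condition proportions
  and their contrasts are computed draw-wise on the back-transformed scale.
* **Probe RT** — Gaussian model of log RT (instruction, optionally
  instruction × task with the no-memory-task baseline as control cell)
  with participant random intercepts.  The compound-symmetry marginal
  likelihood is evaluated in closed form from per-participant sufficient
  statistics; ms-scale condition means are `exp` of the log-scale draws.
* **Absolute color error** — the same Gaussian machinery on |e| in
  degrees.  This treats a (0, 180)-bounded mean as Gaussian — a documented
  approximation; the von Mises dispersion model is the principled circular
  alternative and is also provided.
* **von Mises dispersion** — signed errors as zero-mean von Mises with
  `log κ = γ_F + γ_R·[R] + v_p`; the circular sufficient statistics
  (Σ cos e, n per participant × condition) make the quadrature cheap, and
  dispersion is reported as σ in degrees.

## Synthetic experiments

The generator emulates four designs: (e1) 20 participants, 15 R / 15 F
studied items plus 30 foils, probes on 11 of 15 study trials per
instruction, old/new recognition; (e2) 24 participants, adds the color
wheel and two 12-trial baseline RT blocks; (e3) 36 participants,
remember/know/no; (e4) 33 participants, 60 R / 60 F, color report only.
Study-trial event schedules are recorded per design; the probe-design
events sum to 7 400 ms while the documented total is 7 800 ms, so the
schedule helper returns the component sum and flags the discrepancy
rather than guessing at the missing interval.

Generative defaults are the published group-level estimates: ρ_R = .65,
ρ_F = .51, σ_R = 30.24°, σ_F = 38.73°; recognition coefficients
(−0.39, 0.43, 0.97) for (foil intercept, F, R), remember coefficients
(−1.93, 0.64, 1.02), know coefficients (0.32, 0.61, 0.62); log-RT cell
means 6.11/6.09 (baseline F/R) and 6.32/6.18 (study F/R) with residual
log-SD 0.25.  Quantities no study reports are fixed once at moderate,
recoverable values: between-participant SDs 0.5 (logit recognition), 0.5
(logit ρ), 0.25 (log κ), 0.15 (log RT); trial-level precision spread
`vp_spread = 0.4`, in the range the variable-precision literature
treats as substantial.  Colors are assigned equally spaced with a random
per-participant rotation (this does not affect error distributions);
foils and "new" responses select colors uniformly and are excluded from
all fidelity analyses.  Buffer/practice/familiarization trials produce no
analyzed data and are not simulated.

What the generator does *not* emulate: perceptual non-uniformity of the
color wheel, sequential effects, lapses correlated with RT, response
biases toward category prototypes, or any dependence of the color
response on the recognition response beyond the shared participant
effects.  Passing recovery tests therefore show that the estimators
invert the assumed generative model at realistic sizes — not that real
data satisfy these assumptions.

## Problem sizes used in the checks

Recovery checks simulate the published designs at full size (33 × 120
color trials; 20 × 60 recognition trials).  The continuous-integration
runs use 5 mixture replicates at reduced sampler settings (800 steps,
11 × 11 participant nodes, 9 trial nodes) and 20 logistic replicates;
null-effect calibration uses 200 replicates per model family at 12
participants × 40 trials and 400 steps.  The acceptance script runs one
replicate of each recovery at full quadrature with 1800 steps.

## Known limitations

- The affine-invariant sampler mixes slowly for strongly correlated
  posteriors; diagnostics are computed and surfaced, but heavily
  unbalanced designs may need more steps than the defaults.
- Quadrature marginalization assumes the participant-effect posterior is
  well covered by the Gauss–Hermite grid under the prior scale; extreme
  participants (far outside ±4 prior SDs) would be clipped.
- The pointwise log-likelihood conditions on sampled participant effects;
  marginal-likelihood LOO (integrating participant effects per held-out
  trial) would be an alternative definition and would shift both models'
  elpd similarly.
- `rho → 0` leaves κ unidentified (the posterior returns the prior);
  `rho → 1` with tiny σ pushes κ toward the cap.  Both edges are exercised
  in the tests and documented rather than hidden.
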