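# recallmix

Hierarchical Bayesian modelling of the **probability** and **fidelity** of
long-term memory retrieval in item-method directed forgetting.

In the item-method directed-forgetting paradigm each studied item is
followed by a *Remember* (R) or *Forget* (F) cue; at test, memory for R
items reliably exceeds memory for F items.  When the test is a *continuous
color report* — the participant reproduces the studied color on a wheel —
the angular error `e ∈ (−180°, 180°]` can be modelled as a two-component
mixture:

```
p(e) = ρ · vM(e; κ) + (1 − ρ) / 360
```

where `ρ` is the probability that the trace was retrieved at all (the
response is then a von Mises draw centred on the studied color with
concentration `κ`) and `1 − ρ` the probability of a uniform guess.
Fidelity is reported as the circular standard deviation
`σ = sqrt(−2 ln(I₁(κ)/I₀(κ)))` (in degrees), which falls as `κ` rises.
Instruction conditions get their own group-level `logit(ρ)` and `log(κ)`;
participants contribute random intercepts on both scales, and a
*variable-precision* variant lets `log κ` vary from trial to trial.
Separating `ρ` from `σ` asks whether an instruction to forget merely makes
traces less likely to be retrieved, or also leaves the retrieved traces
less precise.

The package provides, as scikit-learn-style estimators and supporting
functions:

- `datasets` — synthetic item-method experiments (four built-in designs:
  old/new recognition with probe-detection RTs; + color wheel and baseline
  RT blocks; remember/know/no; color-report-only), with the full generative
  structure the analyses assume and CSV round-tripping;
- `preprocess` — the trial-exclusion rules (100 ms RT floor, ±3 SD trim of
  log decision times, the 100–2000 ms probe window) and conditionalization
  of color judgments on claimed recognition / recollection;
- `glm` — multilevel logistic recognition models (foil-intercept dummy
  coding), log-RT models with back-transformation to ms, absolute-error and
  von Mises dispersion models of color error;
- `mixture` — the central `VonMisesUniformMixture` (fixed- and
  variable-precision) with pointwise trial log-likelihoods, plus a
  non-hierarchical EM fitter used as a cross-check;
- `compare` — WAIC and PSIS-LOO from pointwise log-likelihood matrices;
- `pipeline` / `cli` — simulate → preprocess → fit → compare → report from
  a single seeded config (`recallmix --help`).

Posteriors are sampled with an affine-invariant ensemble sampler over the
group-level parameters, with participant random effects marginalized by
Gauss–Hermite quadrature; split R̂ / ESS diagnostics are computed on two
independent ensembles.  See `docs/methods.md` for the model and numerical
details.

## Worked example

```python
from recallmix import (GenParams, experiment_design, generate_experiment,
                       VonMisesUniformMixture)

design = experiment_design("e4")          # 33 participants, 60 R + 60 F
ds = generate_experiment(design, GenParams(), seed=101)
fit = VonMisesUniformMixture(variant="variable", seed=7).fit(ds.test())
for c in ("R", "F"):
    r, s = fit.rho_[c], fit.sigma_[c]
    print(f"{c}: rho {r.median:.3f} {r.hdi95}  sigma {s.median:.1f} {s.hdi95}")
print("rho R-F :", round(fit.rho_contrast("R", "F").median, 3))
print("sigma F-R:", round(fit.sigma_contrast("F", "R").median, 2))
```

Output (a few minutes on one CPU):

```
R: rho 0.673 (0.614, 0.740)  sigma 31.3 (28.38, 34.29)
F: rho 0.489 (0.418, 0.574)  sigma 36.7 (31.68, 43.09)
rho R-F : 0.183
sigma F-R: 5.53
```

The generative truth here was ρ_R = 0.65, ρ_F = 0.51, σ_R = 30.24°,
σ_F = 38.73°: the fit recovers a large R-over-F advantage in the
probability of retrieval *and* a reliable fidelity cost for F items —
both group-level quantities land inside the fit's 95% HDIs.

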