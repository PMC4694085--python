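"""Shared posterior-sampling machinery.

Hierarchical models in this package marginalize participant random effects
with Gauss-Hermite quadrature, leaving a low-dimensional group-level
posterior that is sampled with the affine-invariant ensemble sampler
(:mod:`emcee`).  Two independent ensembles are run from jittered starting
points; split R-hat and effective sample size are computed with arviz,
treating every walker as a chain.  The sampler is an implementation detail:
models expose draws, never the engine.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = ["gauss_hermite", "derive_seed", "run_ensemble", "McmcResult"]


def gauss_hermite(n: int):
    """Nodes/weights for E[f(Z)] with Z ~ N(0,1): ``sum w_i f(x_i)``."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def derive_seed(seed: int, tag: str) -> int:
    """Stable per-stage seed below 2**31 derived from a global seed."""
    return int((seed * 2654435761 + zlib.crc32(tag.encode())) % (2 ** 31))


@dataclass
class McmcResult:
    """Post-warmup draws plus convergence diagnostics."""

    draws: np.ndarray        # (n_draws, ndim), walkers and ensembles flattened
    by_chain: np.ndarray     # (n_chains, n_per_chain, ndim)
    rhat: np.ndarray         # per-parameter split R-hat
    ess: np.ndarray          # per-parameter bulk ESS
    converged: bool
    n_steps: int
    param_names: list | None = None

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def _diagnostics(by_chain: np.ndarray):
    import arviz as az

    idata = az.convert_to_inference_data(by_chain)
    rhat = az.rhat(idata).x.values
    ess = az.ess(idata).x.values
    return np.atleast_1d(rhat), np.atleast_1d(ess)


def run_ensemble(log_prob, ndim: int, init_center, init_scale, seed: int,
                 n_walkers: int | None = None, n_steps: int = 1200,
                 n_warmup: int | None = None, n_ensembles: int = 2,
                 param_names=None, rhat_max: float = 1.01) -> McmcResult:
    """Sample ``log_prob`` (vectorized over rows of a coords matrix).

    ``init_center``/``init_scale`` set the Gaussian jitter of the walkers'
    starting points.  Returns all post-warmup draws from ``n_ensembles``
    independently seeded ensembles; ``converged`` is False when any
    parameter's split R-hat is >= ``rhat_max`` (results are still returned).
    """
    import emcee

    init_center = np.asarray(init_center, dtype=float)
    init_scale = np.broadcast_to(np.asarray(init_scale, dtype=float), (ndim,))
    if n_walkers is None:
        n_walkers = max(2 * ndim + 2, 16)
    n_walkers += n_walkers % 2
    if n_warmup is None:
        n_warmup = n_steps // 2

    chains = []
    for e in range(n_ensembles):
        rng = np.random.RandomState(derive_seed(seed, f"ensemble-{e}"))
        p0 = init_center + init_scale * rng.randn(n_walkers, ndim)
        lp0 = np.asarray(log_prob(p0))
        bad = ~np.isfinite(lp0)
        tries = 0
        while bad.any() and tries < 50:
            p0[bad] = init_center + 0.5 * init_scale * rng.randn(int(bad.sum()), ndim)
            lp0[bad] = np.asarray(log_prob(p0[bad]))
            bad = ~np.isfinite(lp0)
            tries += 1
        if bad.any():
            raise RuntimeError("could not find finite starting points")
        sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True)
        sampler.random_state = rng.get_state()
        sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
        # each independent ensemble is one chain; pool its walkers in step
        # order so split R-hat still contrasts early vs late draws
        chain = sampler.get_chain()[n_warmup:]  # (steps, walkers, ndim)
        chains.append(chain.reshape(-1, ndim))
    by_chain = np.stack(chains, axis=0)
    rhat, ess = _diagnostics(by_chain)
    draws = by_chain.reshape(-1, ndim)
    return McmcResult(draws=draws, by_chain=by_chain, rhat=rhat, ess=ess,
                      converged=bool(np.all(rhat < rhat_max)),
                      n_steps=n_steps, param_names=list(param_names) if param_names else None)
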