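"""Hierarchical von Mises + uniform mixture of continuous color report.

The model separates the *probability* of memory retrieval from the
*fidelity* of retrieved traces.  Each signed error ``e`` (degrees) on a
test trial is, with probability ``rho``, a draw from a zero-mean von Mises
with concentration ``kappa`` (the trace was retrieved), and otherwise a
uniform guess on the wheel:

    p(e) = rho * vM(e; kappa) + (1 - rho) / 360

Instruction conditions (R, F) have their own group-level ``logit(rho)`` and
``log(kappa)``; participants contribute random intercepts on both scales
(shared across conditions).  The *variable-precision* variant additionally
lets ``log kappa`` vary from trial to trial around the participant value
with SD ``vp_spread``; the trial-level concentration is integrated out by
Gauss-Hermite quadrature.  Fidelity is reported as the circular SD sigma
(degrees), converted from kappa draw-wise.

Participant random effects are marginalized on a tensor-product
Gauss-Hermite grid; the likelihood is evaluated on a 1-degree error grid so
participant sums reduce to a matrix product (errors are rounded to the
nearest degree, negligible relative to sigma >= 25 degrees).  Pointwise
trial log-likelihoods for WAIC / PSIS-LOO condition on participant effects
sampled from their conditional posterior on the same grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, i0e, logit, logsumexp
from sklearn.base import BaseEstimator

from ._engine import derive_seed, gauss_hermite, run_ensemble
from .circular import KAPPA_MAX, bessel_ratio, kappa_to_sigma, vm_density
from .summaries import PosteriorSummary

__all__ = ["mixture_density", "VonMisesUniformMixture", "fit_mixture",
           "em_fit_mixture", "pointwise_loglik"]

_CONDS = ("F", "R")


def mixture_density(error_deg, rho, kappa):
    """Mixture density per degree: ``rho * vM + (1 - rho)/360``."""
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must be in [0, 1]")
    return rho * vm_density(error_deg, kappa) + (1.0 - rho) / 360.0


def em_fit_mixture(errors_deg, tol=1e-10, max_iter=2000):
    """Maximum-likelihood (rho, kappa) for the collapsed, non-hierarchical
    fixed-precision mixture, by expectation-maximization.

    The memory component is centred at zero by design; the M-step inverts
    the Bessel ratio ``A(kappa) = I1/I0`` on the responsibility-weighted
    resultant length.  Used as an independent cross-check and to initialize
    the hierarchical sampler.
    """
    e = np.asarray(errors_deg, dtype=float)
    c = np.cos(np.radians(e))
    rho, kappa = 0.5, 5.0
    for _ in range(max_iter):
        f_mem = vm_density(e, kappa)
        num = rho * f_mem
        resp = num / (num + (1.0 - rho) / 360.0)
        rho_new = float(resp.mean())
        rbar = float(np.clip((resp * c).sum() / max(resp.sum(), 1e-12), 0.0, 0.999999))
        if rbar <= bessel_ratio(1e-8):
            kappa_new = 1e-8
        else:
            kappa_new = brentq(lambda k: bessel_ratio(k) - rbar, 1e-8, KAPPA_MAX)
        if abs(rho_new - rho) < tol and abs(kappa_new - kappa) < tol * max(kappa, 1.0):
            rho, kappa = rho_new, kappa_new
            break
        rho, kappa = rho_new, kappa_new
    return rho, kappa


def _bin_errors(errors_deg):
    """Map signed errors in (-180, 180] to 1-degree bin indices 0..359."""
    b = np.rint(np.asarray(errors_deg, dtype=float)).astype(int)
    b[b == -180] = 180
    return b + 179


_BIN_COS = np.cos(np.radians(np.arange(360) - 179.0))
_LOG360 = np.log(360.0)


class VonMisesUniformMixture(BaseEstimator):
    """Hierarchical two-component mixture of signed color-report errors.

    Parameters
    ----------
    variant : {"variable", "fixed"}
        Whether trial-level precision varies (log-normal around the
        participant concentration) or is fixed per participant x condition.
    n_quad_participant : int
        Gauss-Hermite nodes per random-effect dimension (the grid is the
        tensor product over the rho and kappa intercepts).
    n_quad_trial : int
        Gauss-Hermite nodes for the trial-level concentration integral
        (variable variant only).
    n_loglik_draws : int
        Posterior draws retained for the pointwise log-likelihood matrix.

    Fitted attributes
    -----------------
    rho_, sigma_, kappa_ : dict condition -> PosteriorSummary
    vp_spread_ : PosteriorSummary (variable variant)
    pointwise_loglik_ : ndarray (n_loglik_draws, n_trials)
    diagnostics_ : dict with split R-hat, ESS, convergence flag
    """

    def __init__(self, variant="variable", n_quad_participant=15,
                 n_quad_trial=11, prior_rho_scale=1.5,
                 prior_logkappa_loc=np.log(10.0), prior_logkappa_scale=1.0,
                 prior_sd_scale=0.5, n_steps=1500, n_warmup=None,
                 n_walkers=16, n_ensembles=2, n_loglik_draws=400, seed=0):
        self.variant = variant
        self.n_quad_participant = n_quad_participant
        self.n_quad_trial = n_quad_trial
        self.prior_rho_scale = prior_rho_scale
        self.prior_logkappa_loc = prior_logkappa_loc
        self.prior_logkappa_scale = prior_logkappa_scale
        self.prior_sd_scale = prior_sd_scale
        self.n_steps = n_steps
        self.n_warmup = n_warmup
        self.n_walkers = n_walkers
        self.n_ensembles = n_ensembles
        self.n_loglik_draws = n_loglik_draws
        self.seed = seed

    # ------------------------------------------------------------------
    def _memory_density(self, logm, tau):
        """Per-degree memory-component density on the error grid.

        ``logm``: (..., ) log concentration centres; returns (..., 360).
        The variable variant integrates trial-level log-kappa ~
        Normal(logm, tau) with Gauss-Hermite quadrature.
        """
        if self.variant == "fixed":
            kap = np.exp(np.minimum(logm, np.log(KAPPA_MAX)))[..., None]
            return np.exp(kap * _BIN_COS - (np.log(i0e(kap)) + kap) - _LOG360)
        z, wz = self._gh_trial
        lk = logm[..., None] + tau[(...,) + (None,) * (logm.ndim - tau.ndim + 1)] * z
        kap = np.exp(np.minimum(lk, np.log(KAPPA_MAX)))[..., None]
        f = np.exp(kap * _BIN_COS - (np.log(i0e(kap)) + kap) - _LOG360)
        return np.einsum("...jb,j->...b", f, wz, optimize=True)

    def _unpack(self, theta):
        a = theta[:, 0:2]          # logit rho, order (F, R)
        g = theta[:, 2:4]          # log kappa, order (F, R)
        su = np.exp(theta[:, 4])
        sv = np.exp(theta[:, 5])
        tau = np.exp(theta[:, 6]) if self.variant == "variable" else np.zeros(len(theta))
        return a, g, su, sv, tau

    def _node_logliks(self, theta, counts):
        """Per-participant log-likelihood on the random-effect grid.

        Returns ``(S, logmix)`` where ``S`` is (W, Ku, Kv, P) and ``logmix``
        is a dict condition -> (W, Ku, Kv, 360) log mixture density.
        """
        a, g, su, sv, tau = self._unpack(theta)
        qu, _ = self._gh_u
        qv, _ = self._gh_v
        W = theta.shape[0]
        P = counts[_CONDS[0]].shape[0]
        S = np.zeros((W, qu.size, qv.size, P))
        logmix = {}
        for ci, cond in enumerate(_CONDS):
            rho = expit(a[:, ci, None] + su[:, None] * qu)          # (W, Ku)
            logm = g[:, ci, None] + sv[:, None] * qv                # (W, Kv)
            F = self._memory_density(logm, tau)                     # (W, Kv, 360)
            mix = (rho[:, :, None, None] * F[:, None, :, :]
                   + ((1.0 - rho) / 360.0)[:, :, None, None])
            # floor keeps log finite when rho -> 1 and the memory density
            # underflows at the far side of the wheel
            lm = np.log(np.maximum(mix, 1e-300))
            logmix[cond] = lm
            flat = lm.reshape(W * qu.size * qv.size, 360)
            S += (flat @ counts[cond].T).reshape(W, qu.size, qv.size, P)
        return S, logmix

    def _log_prob(self, theta):
        theta = np.atleast_2d(theta)
        bad = np.abs(theta).max(axis=1) > 30.0
        if bad.all():
            return np.full(len(theta), -np.inf)
        S, _ = self._node_logliks(np.where(bad[:, None], 0.0, theta),
                                  self._counts)
        M = logsumexp(S + self._logw2[None, :, :, None], axis=(1, 2))
        ll = M.sum(axis=1)
        a, g, su, sv, tau = self._unpack(theta)
        lp = (-0.5 * (a / self.prior_rho_scale) ** 2).sum(axis=1)
        lp += (-0.5 * ((g - self.prior_logkappa_loc)
                       / self.prior_logkappa_scale) ** 2).sum(axis=1)
        lp += -0.5 * (su / self.prior_sd_scale) ** 2 + theta[:, 4]
        lp += -0.5 * (sv / self.prior_sd_scale) ** 2 + theta[:, 5]
        if self.variant == "variable":
            lp += -0.5 * (tau / self.prior_sd_scale) ** 2 + theta[:, 6]
        out = ll + lp
        out[bad] = -np.inf
        return out

    # ------------------------------------------------------------------
    def fit(self, records: pd.DataFrame, y=None):
        if self.variant not in ("fixed", "variable"):
            raise ValueError(f"unknown variant {self.variant!r}")
        df = records[records["signed_error"].notna()
                     & records["item_type"].isin(_CONDS)].copy()
        present = set(df["item_type"].unique())
        if present != set(_CONDS):
            raise ValueError(f"need both conditions {_CONDS}, have {sorted(present)}")
        if df["participant"].nunique() < 2:
            raise ValueError("need >= 2 participants")

        pids, pidx = np.unique(df["participant"].to_numpy(), return_inverse=True)
        P = pids.size
        bins = _bin_errors(df["signed_error"].to_numpy())
        cond_idx = (df["item_type"] == "R").to_numpy().astype(int)
        counts = {}
        for ci, cond in enumerate(_CONDS):
            m = cond_idx == ci
            counts[cond] = np.zeros((P, 360))
            np.add.at(counts[cond], (pidx[m], bins[m]), 1.0)
        self._counts = counts
        self._trials = (pidx, cond_idx, bins)
        self.participants_ = pids
        self._gh_u = gauss_hermite(self.n_quad_participant)
        self._gh_v = gauss_hermite(self.n_quad_participant)
        self._gh_trial = gauss_hermite(self.n_quad_trial)
        wu, wv = self._gh_u[1], self._gh_v[1]
        self._logw2 = np.log(wu[:, None] * wv[None, :])

        # EM on the pooled errors per condition gives starting values
        init = np.zeros(6 + (self.variant == "variable"))
        for ci, cond in enumerate(_CONDS):
            e_c = df.loc[df["item_type"] == cond, "signed_error"].to_numpy()
            r0, k0 = em_fit_mixture(e_c, tol=1e-6, max_iter=200)
            init[ci] = logit(np.clip(r0, 0.05, 0.95))
            init[2 + ci] = np.log(np.clip(k0, 0.1, KAPPA_MAX / 2))
        init[4], init[5] = np.log(0.4), np.log(0.25)
        if self.variant == "variable":
            init[6] = np.log(0.3)

        names = ["logit_rho_F", "logit_rho_R", "log_kappa_F", "log_kappa_R",
                 "ranef_sd_rho", "ranef_sd_logkappa"]
        if self.variant == "variable":
            names.append("vp_spread")
        res = run_ensemble(
            self._log_prob, len(init), init, 0.08, seed=self.seed,
            n_walkers=self.n_walkers, n_steps=self.n_steps,
            n_warmup=self.n_warmup, n_ensembles=self.n_ensembles,
            param_names=names)
        if not res.converged:
            warnings.warn(
                f"mixture fit: split R-hat up to {res.rhat.max():.3f} (>= 1.01); "
                "results returned but treat with caution", RuntimeWarning)
        self.mcmc_ = res
        self.diagnostics_ = {
            "rhat": dict(zip(names, np.round(res.rhat, 4))),
            "ess": dict(zip(names, np.round(res.ess, 1))),
            "converged": res.converged,
            "n_draws": res.n_draws,
        }

        d = res.draws
        self.draws_ = {n: d[:, i] for i, n in enumerate(names)}
        rho_draws = {c: expit(d[:, ci]) for ci, c in enumerate(_CONDS)}
        kap_draws = {c: np.exp(np.minimum(d[:, 2 + ci], np.log(KAPPA_MAX)))
                     for ci, c in enumerate(_CONDS)}
        sig_draws = {c: kappa_to_sigma(kap_draws[c]) for c in _CONDS}
        self._rho_draws, self._sigma_draws = rho_draws, sig_draws
        self.rho_ = {c: PosteriorSummary(f"rho_{c}", rho_draws[c], "proportion")
                     for c in _CONDS}
        self.kappa_ = {c: PosteriorSummary(f"kappa_{c}", kap_draws[c], "raw")
                       for c in _CONDS}
        self.sigma_ = {c: PosteriorSummary(f"sigma_{c}", sig_draws[c], "degrees")
                       for c in _CONDS}
        self.ranef_sd_ = {
            "rho": PosteriorSummary("ranef_sd_rho", np.exp(d[:, 4]), "logit"),
            "logkappa": PosteriorSummary("ranef_sd_logkappa", np.exp(d[:, 5]), "log"),
        }
        if self.variant == "variable":
            self.vp_spread_ = PosteriorSummary("vp_spread", np.exp(d[:, 6]), "log")
        self.pointwise_loglik_ = self._pointwise_loglik()
        return self

    # ------------------------------------------------------------------
    def rho_draws(self, cond):
        return self._rho_draws[cond]

    def sigma_draws(self, cond):
        return self._sigma_draws[cond]

    def rho_contrast(self, a="R", b="F") -> PosteriorSummary:
        """Draw-wise difference of back-transformed rho (default R - F)."""
        return PosteriorSummary(f"rho_{a}-{b}",
                                self._rho_draws[a] - self._rho_draws[b],
                                "proportion")

    def sigma_contrast(self, a="F", b="R") -> PosteriorSummary:
        """Draw-wise difference of sigma in degrees (default F - R)."""
        return PosteriorSummary(f"sigma_{a}-{b}",
                                self._sigma_draws[a] - self._sigma_draws[b],
                                "degrees")

    def _pointwise_loglik(self):
        """Trial-level conditional log-likelihood matrix (draws x trials).

        For each retained posterior draw, participant random effects are
        sampled from their conditional posterior on the quadrature grid;
        each trial's log density is then evaluated at its error given those
        effects (marginal over trial-level precision in the variable
        variant).
        """
        pidx, cond_idx, bins = self._trials
        d = self.mcmc_.draws
        n_keep = min(self.n_loglik_draws, d.shape[0])
        keep = np.linspace(0, d.shape[0] - 1, n_keep).astype(int)
        rng = np.random.default_rng(derive_seed(self.seed, "pointwise"))
        T = pidx.size
        out = np.empty((n_keep, T))
        Ku = self._gh_u[0].size
        Kv = self._gh_v[0].size
        batch = max(1, int(2e6 / (Ku * Kv * 360)))
        for start in range(0, n_keep, batch):
            sel = keep[start:start + batch]
            theta = d[sel]
            S, logmix = self._node_logliks(theta, self._counts)
            logpost = S + self._logw2[None, :, :, None]      # (B, Ku, Kv, P)
            B, _, _, P = logpost.shape
            flat = logpost.reshape(B, Ku * Kv, P)
            flat = flat - logsumexp(flat, axis=1, keepdims=True)
            probs = np.exp(flat)                              # (B, K2, P)
            cum = probs.cumsum(axis=1)
            u = rng.random((B, 1, P))
            node = (u > cum).sum(axis=1)                      # (B, P)
            iu, iv = np.unravel_index(node, (Ku, Kv))
            for bi in range(B):
                row = np.empty(T)
                for ci, cond in enumerate(_CONDS):
                    m = cond_idx == ci
                    row[m] = logmix[cond][bi, iu[bi, pidx[m]],
                                          iv[bi, pidx[m]], bins[m]]
                out[start + bi] = row
        return out


def fit_mixture(records, variant="variable", **kwargs) -> VonMisesUniformMixture:
    """Thin functional wrapper over :class:`VonMisesUniformMixture`."""
    return VonMisesUniformMixture(variant=variant, **kwargs).fit(records)


def pointwise_loglik(fit: VonMisesUniformMixture) -> np.ndarray:
    """The (draws x trials) pointwise log-likelihood matrix of a fit."""
    if not hasattr(fit, "pointwise_loglik_"):
        raise RuntimeError("model is not fitted")
    return fit.pointwise_loglik_
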