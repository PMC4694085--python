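"""Hierarchical regression models for recognition, RT, and color-error data.

Every model here is a Bayesian multilevel regression with participant
random intercepts:

* :class:`MultilevelLogistic` -- binary responses (old/new, remember/not,
  know/no) against item-type dummies, foil (or the first listed level) as
  the intercept.
* :class:`LogRtModel` -- linear model on log RT with instruction
  (optionally instruction x task with the no-memory-task baseline) as
  predictors; condition means are back-transformed to ms draw-wise.
* :class:`AbsoluteErrorModel` -- linear model of the mean absolute angular
  error (degrees) per instruction.
* :class:`VonMisesDispersionModel` -- signed errors as zero-mean von Mises
  with condition-specific concentration on a log link; dispersion is
  reported as the circular SD sigma in degrees.

Participant intercepts are marginalized with Gauss-Hermite quadrature
(exactly, in the Gaussian-response cases), leaving a small group-level
posterior sampled by the shared ensemble engine.  Priors are weakly
informative: Normal(0, 2.5) on fixed effects (scaled by the response SD for
the Gaussian models, so the scale refers to standardized effects) and
half-Normal(0, 1) on random-effect and residual SDs (same scaling).

All back-transformations (logit -> proportion, log -> ms, kappa -> sigma)
are applied draw-wise and only then summarized.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit, i0e, logsumexp
from sklearn.base import BaseEstimator

from ._engine import gauss_hermite, run_ensemble
from .circular import kappa_to_sigma
from .summaries import PosteriorSummary

logger = logging.getLogger(__name__)

__all__ = [
    "MultilevelLogistic", "LogRtModel", "AbsoluteErrorModel",
    "VonMisesDispersionModel", "contrast",
    "fit_multilevel_logistic", "fit_rt_model",
    "fit_absolute_error_model", "fit_vonmises_dispersion",
]


class _HierarchicalModel(BaseEstimator):
    """Shared fitting/summary machinery; subclasses define the likelihood."""

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise RuntimeError("model is not fitted")

    def _sample(self, log_prob, ndim, init_center, init_scale, names):
        res = run_ensemble(
            log_prob, ndim, init_center, init_scale,
            seed=self.seed, n_walkers=self.n_walkers, n_steps=self.n_steps,
            n_ensembles=self.n_ensembles, param_names=names)
        if not res.converged:
            warnings.warn(
                f"{type(self).__name__}: split R-hat up to {res.rhat.max():.3f} "
                "(>= 1.01); treat results with caution", RuntimeWarning)
        self.mcmc_ = res
        self.diagnostics_ = {
            "rhat": dict(zip(names, np.round(res.rhat, 4))),
            "ess": dict(zip(names, np.round(res.ess, 1))),
            "converged": res.converged,
            "n_draws": res.n_draws,
        }
        return res.draws

    def condition_mean_draws(self, condition):
        """Posterior draws of the named condition mean on its natural scale."""
        self._check_fitted()
        try:
            return self._condition_draws[condition]
        except KeyError:
            raise KeyError(f"unknown condition {condition!r}; "
                           f"have {sorted(self._condition_draws)}")

    def contrast(self, a, b, scale=None) -> PosteriorSummary:
        """Draw-wise difference ``a - b`` of back-transformed condition means."""
        d = self.condition_mean_draws(a) - self.condition_mean_draws(b)
        return PosteriorSummary(name=f"{a}-{b}", draws=d,
                                scale=scale or self._natural_scale)

    def summaries(self) -> dict:
        self._check_fitted()
        out = {k: v.to_dict() for k, v in self.coefficients_.items()}
        out.update({f"mean[{k}]": v.to_dict()
                    for k, v in self.condition_means_.items()})
        return out


def contrast(model: _HierarchicalModel, a, b, scale=None) -> PosteriorSummary:
    """Module-level convenience wrapper for :meth:`contrast`."""
    return model.contrast(a, b, scale=scale)


def _halfnormal_logprior(sd, scale):
    return -0.5 * (sd / scale) ** 2


class MultilevelLogistic(_HierarchicalModel):
    """Multilevel logistic regression of a binary response on item type.

    ``item_types`` sets the dummy coding: the first level is the intercept,
    the rest get slope coefficients.  ``positive`` lists the response
    value(s) coded 1.  Participant random intercepts are integrated out by
    Gauss-Hermite quadrature of the binomial likelihood.
    """

    _natural_scale = "proportion"

    def __init__(self, positive=("old",), item_types=("foil", "F", "R"),
                 response_col="recognition_response", prior_scale=2.5,
                 ranef_prior_scale=1.0, n_quad=21, n_steps=1200,
                 n_walkers=None, n_ensembles=2, seed=0):
        self.positive = positive
        self.item_types = item_types
        self.response_col = response_col
        self.prior_scale = prior_scale
        self.ranef_prior_scale = ranef_prior_scale
        self.n_quad = n_quad
        self.n_steps = n_steps
        self.n_walkers = n_walkers
        self.n_ensembles = n_ensembles
        self.seed = seed

    def fit(self, records: pd.DataFrame, y=None):
        types = list(self.item_types)
        pos = {self.positive} if isinstance(self.positive, str) else set(self.positive)
        df = records[(records["phase"] == "test")
                     & records[self.response_col].notna()
                     & (records[self.response_col] != "none")
                     & records["item_type"].isin(types)]
        if df["participant"].nunique() < 2:
            raise ValueError("need >= 2 participants")
        y01 = df[self.response_col].isin(pos).astype(int)
        counts = (df.assign(_y=y01)
                    .groupby(["participant", "item_type"], observed=True)["_y"]
                    .agg(["sum", "count"]).unstack("item_type"))
        for t in types:
            if ("count", t) not in counts.columns or counts[("count", t)].fillna(0).sum() == 0:
                raise ValueError(f"condition {t!r} has zero trials")
        Y = np.nan_to_num(counts["sum"].reindex(columns=types).to_numpy(float))
        N = np.nan_to_num(counts["count"].reindex(columns=types).to_numpy(float))
        if (Y.sum(0) == 0).any() or (Y.sum(0) == N.sum(0)).any():
            logger.warning("complete or quasi-complete separation in a condition; "
                           "the prior dominates that coefficient")

        k = len(types)
        nodes, qw = gauss_hermite(self.n_quad)
        logqw = np.log(qw)
        # design on the logit scale: eta_type = beta0 + beta_type
        dummy = np.eye(k)
        dummy[:, 0] = 1.0

        def log_prob(theta):
            theta = np.atleast_2d(theta)
            bad = np.abs(theta).max(axis=1) > 30.0
            theta = np.where(bad[:, None], 0.0, theta)
            beta, log_su = theta[:, :k], theta[:, k]
            su = np.exp(log_su)
            eta = beta @ dummy.T  # (W, k types)
            z = eta[:, :, None] + su[:, None, None] * nodes  # (W, T, Q)
            log_p = -np.logaddexp(0.0, -z)
            log_1mp = -np.logaddexp(0.0, z)
            # (W, Q, P): binomial log-lik at each node for each participant
            ll_nodes = (np.einsum("pt,wtq->wqp", Y, log_p, optimize=True)
                        + np.einsum("pt,wtq->wqp", N - Y, log_1mp, optimize=True))
            ll = logsumexp(ll_nodes + logqw[None, :, None], axis=1).sum(axis=1)
            lp = (-0.5 * (beta / self.prior_scale) ** 2).sum(axis=1)
            lp += _halfnormal_logprior(su, self.ranef_prior_scale) + log_su
            out = ll + lp
            out[bad] = -np.inf
            return out

        # crude initial values from pooled proportions
        p_pool = np.clip(Y.sum(0) / np.maximum(N.sum(0), 1), 0.02, 0.98)
        eta0 = np.log(p_pool / (1 - p_pool))
        init = np.r_[eta0[0], eta0[1:] - eta0[0], np.log(0.3)]
        names = [f"b_{t}" for t in types] + ["ranef_sd"]
        draws = self._sample(log_prob, k + 1, init, 0.1, names)

        beta_d = draws[:, :k]
        self.draws_ = {n: draws[:, i] for i, n in enumerate(names)}
        self.draws_["ranef_sd"] = np.exp(draws[:, k])
        self.coefficients_ = {
            f"b_{t}": PosteriorSummary(f"b_{t}", beta_d[:, i], "logit")
            for i, t in enumerate(types)
        }
        self.ranef_sd_ = PosteriorSummary("ranef_sd", self.draws_["ranef_sd"], "logit")
        eta_cond = beta_d @ dummy.T
        self._condition_draws = {t: expit(eta_cond[:, i]) for i, t in enumerate(types)}
        self.condition_means_ = {
            t: PosteriorSummary(t, self._condition_draws[t], "proportion")
            for t in types
        }
        return self


class _LinearMixedModel(_HierarchicalModel):
    """Gaussian LMM with participant random intercepts, exact marginal lik.

    Subclasses provide the response vector, the design matrix, and the
    condition -> design-row map.  The compound-symmetry marginal likelihood
    is evaluated in closed form from per-participant sufficient statistics.
    """

    def __init__(self, prior_scale=2.5, ranef_prior_scale=1.0, n_steps=1200,
                 n_walkers=None, n_ensembles=2, seed=0):
        self.prior_scale = prior_scale
        self.ranef_prior_scale = ranef_prior_scale
        self.n_steps = n_steps
        self.n_walkers = n_walkers
        self.n_ensembles = n_ensembles
        self.seed = seed

    # subclass API ---------------------------------------------------------
    def _design(self, records):  # pragma: no cover - abstract
        """Return (y, X, participant_ids, condition_rows: dict name -> x)."""
        raise NotImplementedError

    def _transform(self, draws):
        """Natural-scale transform of condition-mean draws (default identity)."""
        return draws

    # ----------------------------------------------------------------------
    def fit(self, records: pd.DataFrame, y=None):
        yv, X, part, cond_rows = self._design(records)
        if len(yv) == 0:
            raise ValueError("no usable trials")
        if pd.unique(part).size < 2:
            raise ValueError("need >= 2 participants")
        k = X.shape[1]
        sd_y = float(np.std(yv))
        if sd_y <= 1e-8 * (1.0 + float(np.abs(yv).mean())):
            # (near-)constant response: fall back to a unit-or-larger scale
            sd_y = max(1.0, float(np.abs(yv).mean()))
        b_scale = self.prior_scale * sd_y
        s_scale = self.ranef_prior_scale * sd_y

        # per-participant sufficient statistics
        pids, pidx = np.unique(part, return_inverse=True)
        P = pids.size
        n_p = np.bincount(pidx).astype(float)
        Sy = np.bincount(pidx, weights=yv)
        Syy = np.bincount(pidx, weights=yv ** 2)
        SX = np.zeros((P, k))
        SXy = np.zeros((P, k))
        SXX = np.zeros((P, k, k))
        for j in range(k):
            SX[:, j] = np.bincount(pidx, weights=X[:, j])
            SXy[:, j] = np.bincount(pidx, weights=X[:, j] * yv)
            for l in range(j, k):
                v = np.bincount(pidx, weights=X[:, j] * X[:, l])
                SXX[:, j, l] = SXX[:, l, j] = v

        def log_prob(theta):
            theta = np.atleast_2d(theta)
            # log-SDs bounded to [-8, 8] (in units of the response SD);
            # keeps the degenerate zero-residual spike from running away
            bad = (np.abs(theta[:, k:]).max(axis=1) > 8.0) \
                | (np.abs(theta[:, :k]).max(axis=1) > 1e6)
            theta = np.where(bad[:, None], 0.0, theta)
            beta = theta[:, :k]
            su = np.exp(theta[:, k])
            se = np.exp(theta[:, k + 1])
            r_sum = Sy[None, :] - beta @ SX.T                      # (W, P)
            r_ss = (Syy[None, :] - 2 * beta @ SXy.T
                    + np.einsum("wj,pjl,wl->wp", beta, SXX, beta, optimize=True))
            r_ss = np.maximum(r_ss, 0.0)
            se2 = se[:, None] ** 2
            tot = se2 + n_p[None, :] * su[:, None] ** 2
            within = r_ss - r_sum ** 2 / n_p[None, :]
            ll = -0.5 * (n_p[None, :] * np.log(2 * np.pi)
                         + (n_p[None, :] - 1) * np.log(se2)
                         + np.log(tot)
                         + within / se2
                         + r_sum ** 2 / (n_p[None, :] * tot))
            ll = ll.sum(axis=1)
            lp = (-0.5 * (beta / b_scale) ** 2).sum(axis=1)
            lp += _halfnormal_logprior(su, s_scale) + theta[:, k]
            lp += _halfnormal_logprior(se, s_scale) + theta[:, k + 1]
            out = ll + lp
            out[bad] = -np.inf
            return out

        beta0, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid_sd = float(np.std(yv - X @ beta0)) or 1e-3
        init = np.r_[beta0, np.log(max(resid_sd * 0.5, 1e-3)),
                     np.log(max(resid_sd, 1e-3))]
        names = [f"b{j}" for j in range(k)] + ["ranef_sd", "resid_sd"]
        names[:len(self._coef_names)] = self._coef_names
        draws = self._sample(log_prob, k + 2, init, 0.05, names)

        beta_d = draws[:, :k]
        self.draws_ = {n: draws[:, i] for i, n in enumerate(names)}
        self.draws_["ranef_sd"] = np.exp(draws[:, k])
        self.draws_["resid_sd"] = np.exp(draws[:, k + 1])
        self.coefficients_ = {
            n: PosteriorSummary(n, beta_d[:, j], self._link_scale)
            for j, n in enumerate(names[:k])
        }
        self.ranef_sd_ = PosteriorSummary("ranef_sd", self.draws_["ranef_sd"],
                                          self._link_scale)
        self._condition_link_draws = {c: beta_d @ np.asarray(x, float)
                                      for c, x in cond_rows.items()}
        self._condition_draws = {c: self._transform(d)
                                 for c, d in self._condition_link_draws.items()}
        self.condition_means_ = {
            c: PosteriorSummary(c, d, self._natural_scale)
            for c, d in self._condition_draws.items()
        }
        return self

    def condition_link_draws(self, condition):
        """Condition-mean draws on the link (model) scale."""
        self._check_fitted()
        return self._condition_link_draws[condition]


class LogRtModel(_LinearMixedModel):
    """Log-RT mixed model: instruction, optionally x task with a baseline.

    Fit to probe trials (pre-filtered).  With ``with_task=True`` the design
    is F-control intercept, instruction (R vs F), task (study vs control),
    and their interaction; condition means are reported per
    (instruction, task) cell both on the log scale and back-transformed to
    ms (draw-wise).
    """

    _natural_scale = "ms"
    _link_scale = "log"

    def __init__(self, with_task=False, rt_col="probe_rt_ms", **kw):
        super().__init__(**kw)
        self.with_task = with_task
        self.rt_col = rt_col

    @property
    def _coef_names(self):
        if self.with_task:
            return ["intercept_F_control", "instruction_R", "task_study",
                    "interaction"]
        return ["intercept_F", "instruction_R"]

    def _design(self, records):
        df = records[records[self.rt_col].notna()
                     & records["item_type"].isin(["R", "F"])]
        y = np.log(df[self.rt_col].to_numpy(float))
        is_r = (df["item_type"] == "R").astype(float).to_numpy()
        if self.with_task:
            is_study = (df["phase"] == "study").astype(float).to_numpy()
            cells = {"F:control": [1, 0, 0, 0], "R:control": [1, 1, 0, 0],
                     "F:study": [1, 0, 1, 0], "R:study": [1, 1, 1, 1]}
            for cell, x in cells.items():
                instr, task = cell.split(":")
                m = (is_r == x[1]) & (is_study == x[2])
                if not m.any():
                    raise ValueError(f"empty instruction x task cell {cell!r}")
            X = np.column_stack([np.ones_like(y), is_r, is_study, is_r * is_study])
            return y, X, df["participant"].to_numpy(), cells
        X = np.column_stack([np.ones_like(y), is_r])
        for cond, flag in (("F", 0.0), ("R", 1.0)):
            if not (is_r == flag).any():
                raise ValueError(f"no trials for instruction {cond!r}")
        return y, X, df["participant"].to_numpy(), {"F": [1, 0], "R": [1, 1]}

    def _transform(self, draws):
        return np.exp(draws)


class AbsoluteErrorModel(_LinearMixedModel):
    """Mean absolute color error (degrees) per instruction, F intercept.

    A Gaussian approximation on the (0, 180)-bounded mean absolute error;
    the von Mises dispersion model is the principled circular alternative.
    """

    _natural_scale = "degrees"
    _link_scale = "degrees"
    _coef_names = ["intercept_F", "instruction_R"]

    def _design(self, records):
        df = records[records["signed_error"].notna()
                     & records["item_type"].isin(["R", "F"])]
        per_cond = df.groupby(["participant", "item_type"], observed=True).size()
        if (per_cond < 2).any():
            logger.warning("some participant x condition cells have < 2 "
                           "retained color trials")
        y = np.abs(df["signed_error"].to_numpy(float))
        is_r = (df["item_type"] == "R").astype(float).to_numpy()
        X = np.column_stack([np.ones_like(y), is_r])
        return y, X, df["participant"].to_numpy(), {"F": [1, 0], "R": [1, 1]}


class VonMisesDispersionModel(_HierarchicalModel):
    """Zero-mean von Mises model of signed errors with condition kappas.

    ``log kappa = gamma_F + gamma_R * [R] + v_p`` with participant effects
    ``v_p`` integrated by quadrature; dispersion is reported as the circular
    SD in degrees via the kappa -> sigma conversion applied draw-wise.
    """

    _natural_scale = "degrees"

    def __init__(self, prior_scale=2.5, ranef_prior_scale=1.0, n_quad=21,
                 kappa_cap=500.0, n_steps=1200, n_walkers=None,
                 n_ensembles=2, seed=0):
        self.prior_scale = prior_scale
        self.ranef_prior_scale = ranef_prior_scale
        self.n_quad = n_quad
        self.kappa_cap = kappa_cap
        self.n_steps = n_steps
        self.n_walkers = n_walkers
        self.n_ensembles = n_ensembles
        self.seed = seed

    def fit(self, records: pd.DataFrame, y=None):
        df = records[records["signed_error"].notna()
                     & records["item_type"].isin(["R", "F"])]
        if df["participant"].nunique() < 2:
            raise ValueError("need >= 2 participants")
        e_rad = np.radians(df["signed_error"].to_numpy(float))
        is_r = (df["item_type"] == "R").to_numpy()
        pids, pidx = np.unique(df["participant"].to_numpy(), return_inverse=True)
        P = pids.size
        # sufficient statistics per participant x condition
        Sc = np.zeros((P, 2))
        n_pc = np.zeros((P, 2))
        for c, mask in enumerate((~is_r, is_r)):
            Sc[:, c] = np.bincount(pidx[mask], weights=np.cos(e_rad[mask]),
                                   minlength=P)
            n_pc[:, c] = np.bincount(pidx[mask], minlength=P)
        nodes, qw = gauss_hermite(self.n_quad)
        logqw = np.log(qw)
        log_cap = np.log(self.kappa_cap)

        def log_prob(theta):
            theta = np.atleast_2d(theta)
            bad = np.abs(theta).max(axis=1) > 25.0
            theta = np.where(bad[:, None], 0.0, theta)
            g = theta[:, :2]           # gamma_F, gamma_R (slope)
            sv = np.exp(theta[:, 2])
            logk = np.stack([g[:, 0], g[:, 0] + g[:, 1]], axis=1)  # (W, 2)
            lk = logk[:, None, :] + sv[:, None, None] * nodes[None, :, None]
            lk = np.minimum(lk, log_cap)
            kap = np.exp(lk)           # (W, Q, 2)
            log_i0 = np.log(i0e(kap)) + kap
            # (W, Q, P): sum_c kappa * Sc - n * log(2 pi I0(kappa))
            ll_nodes = (np.einsum("wqc,pc->wqp", kap, Sc, optimize=True)
                        - np.einsum("wqc,pc->wqp", log_i0 + np.log(2 * np.pi),
                                    n_pc, optimize=True))
            ll = logsumexp(ll_nodes + logqw[None, :, None], axis=1).sum(axis=1)
            lp = (-0.5 * (g / self.prior_scale) ** 2).sum(axis=1)
            lp += _halfnormal_logprior(sv, self.ranef_prior_scale) + theta[:, 2]
            out = ll + lp
            out[bad] = -np.inf
            return out

        # moment init from the pooled resultant length per condition
        rbar = np.clip(Sc.sum(0) / np.maximum(n_pc.sum(0), 1), 1e-3, 0.999999)
        from .circular import bessel_ratio
        from scipy.optimize import brentq
        k0 = [self.kappa_cap if r >= bessel_ratio(self.kappa_cap)
              else (brentq(lambda k: bessel_ratio(k) - r, 1e-6, self.kappa_cap)
                    if r > bessel_ratio(1e-6) else 1e-3) for r in rbar]
        init = np.r_[np.log(k0[0]), np.log(k0[1]) - np.log(k0[0]), np.log(0.2)]
        names = ["log_kappa_F", "log_kappa_R_slope", "ranef_sd"]
        draws = self._sample(log_prob, 3, init, 0.1, names)

        self.draws_ = {n: draws[:, i] for i, n in enumerate(names)}
        self.draws_["ranef_sd"] = np.exp(draws[:, 2])
        self.coefficients_ = {
            n: PosteriorSummary(n, draws[:, i], "log")
            for i, n in enumerate(names[:2])
        }
        self.ranef_sd_ = PosteriorSummary("ranef_sd", self.draws_["ranef_sd"], "log")
        logk = {"F": draws[:, 0], "R": draws[:, 0] + draws[:, 1]}
        self.kappa_ = {c: PosteriorSummary(f"kappa_{c}", np.exp(v), "raw")
                       for c, v in logk.items()}
        self._condition_draws = {
            c: kappa_to_sigma(np.minimum(np.exp(v), self.kappa_cap))
            for c, v in logk.items()
        }
        self.condition_means_ = {
            c: PosteriorSummary(f"sigma_{c}", d, "degrees")
            for c, d in self._condition_draws.items()
        }
        return self


# thin functional wrappers ---------------------------------------------------

def fit_multilevel_logistic(records, **kwargs) -> MultilevelLogistic:
    return MultilevelLogistic(**kwargs).fit(records)


def fit_rt_model(records, **kwargs) -> LogRtModel:
    return LogRtModel(**kwargs).fit(records)


def fit_absolute_error_model(records, **kwargs) -> AbsoluteErrorModel:
    return AbsoluteErrorModel(**kwargs).fit(records)


def fit_vonmises_dispersion(records, **kwargs) -> VonMisesDispersionModel:
    return VonMisesDispersionModel(**kwargs).fit(records)
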