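"""Information-criterion model comparison from pointwise log-likelihoods.

Both criteria estimate expected log pointwise predictive density (elpd) for
out-of-sample data from an ``(S draws, T trials)`` matrix of pointwise
log-likelihoods:

* WAIC: ``elpd_t = log mean_s exp(ll_st) - var_s(ll_st)``.
* PSIS-LOO: importance-sampling leave-one-out, with the largest 20% of the
  importance ratios of each trial replaced by quantiles of a generalized
  Pareto distribution fit to that tail (Pareto-smoothed importance
  sampling); the tail shape ``k-hat`` diagnoses unreliable trials.

Comparisons are reported on the elpd scale; ``delta = elpd_a - elpd_b`` with
``se_delta = sqrt(T * var_t(a_t - b_t))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["waic", "psis_loo", "compare", "ComparisonResult"]


def _validate(loglik):
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("loglik must be 2-D (draws x trials)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("loglik contains non-finite entries")
    return ll


def waic(loglik):
    """Widely applicable information criterion on the elpd scale.

    Returns ``(elpd, se, pointwise)`` where ``pointwise[t] = lpd_t - p_t``.
    """
    ll = _validate(loglik)
    n_draws, n_trials = ll.shape
    lpd = logsumexp(ll, axis=0) - np.log(n_draws)
    p_waic = ll.var(axis=0, ddof=1) if n_draws > 1 else np.zeros(n_trials)
    pointwise = lpd - p_waic
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n_trials * pointwise.var(ddof=1))) if n_trials > 1 else 0.0
    return elpd, se, pointwise


def _gpd_fit(x):
    """Generalized-Pareto (shape k, scale sigma) fit to exceedances ``x``.

    Profile-likelihood method of Zhang & Stephens (2009) with a weak prior
    on the shape; ``x`` must be sorted ascending and positive.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    prior_bs, prior_k = 3.0, 10.0
    m_est = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m_est / (np.arange(1, m_est + 1, dtype=float) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.log1p(-b[:, None] * x).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lik = n * (np.log(-(b / k)) - k - 1.0)
    log_lik[~np.isfinite(log_lik)] = -np.inf
    w = 1.0 / np.exp(log_lik - log_lik[:, None]).sum(axis=1)
    w[w < 10 * np.finfo(float).eps] = 0.0
    w /= w.sum()
    b_post = float((b * w).sum())
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post
    # regularize the shape towards 0.5 with prior_k pseudo-observations
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, sigma


def _gpd_quantile(p, k, sigma):
    """Inverse CDF of the generalized Pareto with shape ``k``, scale ``sigma``."""
    p = np.asarray(p, dtype=float)
    if abs(k) < 1e-12:
        q = -np.log1p(-p)
    else:
        q = np.expm1(-k * np.log1p(-p)) / k
    return sigma * q


def _smooth_tail_weights(log_ratios):
    """Pareto-smooth one trial's log importance ratios.

    Returns (smoothed log-weights normalized to max 0, k_hat).  Falls back
    to plain truncated importance sampling when the tail has < 5 points.
    """
    lw = np.asarray(log_ratios, dtype=float)
    s = lw.size
    lw = lw - lw.max()
    # tail size: 20% of draws, capped at 3*sqrt(S) so the generalized-Pareto
    # approximation holds for large draw counts
    n_tail = int(np.ceil(min(0.2 * s, 3.0 * np.sqrt(s))))
    if n_tail < 5:
        warnings.warn("tail too short for Pareto fit; using truncated "
                      "importance sampling", RuntimeWarning, stacklevel=2)
        return np.minimum(lw, 0.0), -np.inf
    order = np.argsort(lw)
    tail_ids = order[-n_tail:]
    cutoff = lw[order[-n_tail - 1]]
    exceed = np.exp(lw[tail_ids]) - np.exp(cutoff)
    if exceed[-1] <= 0 or np.allclose(exceed, 0):
        return np.minimum(lw, 0.0), -np.inf
    k_hat, sigma = _gpd_fit(np.sort(exceed))
    if sigma <= 0 or not np.isfinite(k_hat):
        return np.minimum(lw, 0.0), -np.inf
    probs = (np.arange(1, n_tail + 1) - 0.5) / n_tail
    smoothed = np.log(_gpd_quantile(probs, k_hat, sigma) + np.exp(cutoff))
    # put smoothed values back in the rank order of the original tail
    lw_s = lw.copy()
    lw_s[tail_ids[np.argsort(lw[tail_ids])]] = smoothed
    lw_s = np.minimum(lw_s, 0.0)  # truncate at the (smoothed) maximum
    return lw_s, k_hat


def psis_loo(loglik):
    """PSIS leave-one-out elpd.

    Returns ``(elpd, se, pointwise, pareto_k)``; trials with
    ``pareto_k > 0.7`` have unreliable importance-sampling estimates.
    """
    ll = _validate(loglik)
    n_draws, n_trials = ll.shape
    pointwise = np.empty(n_trials)
    pareto_k = np.empty(n_trials)
    with warnings.catch_warnings():
        warnings.simplefilter("once", RuntimeWarning)
        for t in range(n_trials):
            lw, k_hat = _smooth_tail_weights(-ll[:, t])
            pointwise[t] = logsumexp(lw + ll[:, t]) - logsumexp(lw)
            pareto_k[t] = k_hat
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n_trials * pointwise.var(ddof=1))) if n_trials > 1 else 0.0
    return elpd, se, pointwise, pareto_k


@dataclass
class ComparisonResult:
    """elpd comparison of two models fit to the same trials."""

    method: str
    elpd_a: float
    elpd_b: float
    delta: float
    se_delta: float
    pareto_k_a: np.ndarray | None = None
    pareto_k_b: np.ndarray | None = None
    n_high_k: int = 0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "elpd_a": self.elpd_a,
            "elpd_b": self.elpd_b,
            "delta": self.delta,
            "se_delta": self.se_delta,
            "n_high_k": self.n_high_k,
        }


def compare(loglik_a, loglik_b, method: str = "waic") -> ComparisonResult:
    """Compare two models by elpd difference (``a - b``) over shared trials."""
    ll_a = _validate(loglik_a)
    ll_b = _validate(loglik_b)
    if ll_a.shape[1] != ll_b.shape[1]:
        raise ValueError("models were fit to different numbers of trials")
    ka = kb = None
    if method == "waic":
        elpd_a, _, pw_a = waic(ll_a)
        elpd_b, _, pw_b = waic(ll_b)
    elif method == "psis_loo":
        elpd_a, _, pw_a, ka = psis_loo(ll_a)
        elpd_b, _, pw_b, kb = psis_loo(ll_b)
    else:
        raise ValueError(f"unknown method {method!r}")
    diff = pw_a - pw_b
    n = diff.size
    se = float(np.sqrt(n * diff.var(ddof=1))) if n > 1 else 0.0
    n_high = 0
    for k in (ka, kb):
        if k is not None:
            n_high += int(np.sum(k > 0.7))
    return ComparisonResult(method=method, elpd_a=elpd_a, elpd_b=elpd_b,
                            delta=float(diff.sum()), se_delta=se,
                            pareto_k_a=ka, pareto_k_b=kb, n_high_k=n_high)
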