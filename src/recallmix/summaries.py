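"""Posterior summaries: highest density intervals and summary containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["hdi", "PosteriorSummary", "summarize_draws"]


def hdi(draws, mass: float = 0.95):
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    Parameters
    ----------
    draws : array-like
        Posterior draws for a scalar quantity (>= 100 recommended).
    mass : float
        Probability mass in ``(0, 1)``.

    Returns
    -------
    (lo, hi) : tuple of float
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("no draws")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 + np.arange(n - k + 1)] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


@dataclass
class PosteriorSummary:
    """Draws plus median and 50%/95% HDIs for one named quantity."""

    name: str
    draws: np.ndarray
    scale: str = "raw"  # logit | log | proportion | ms | degrees | raw
    median: float = field(init=False)
    hdi50: tuple = field(init=False)
    hdi95: tuple = field(init=False)

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float).ravel()
        self.median = float(np.median(self.draws))
        self.hdi50 = hdi(self.draws, 0.50)
        self.hdi95 = hdi(self.draws, 0.95)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scale": self.scale,
            "median": self.median,
            "hdi50": list(self.hdi50),
            "hdi95": list(self.hdi95),
        }

    def __repr__(self):  # pragma: no cover - cosmetic
        lo, hi = self.hdi95
        return (f"PosteriorSummary({self.name}: median={self.median:.3g}, "
                f"95% HDI [{lo:.3g}, {hi:.3g}], scale={self.scale})")


def summarize_draws(name, draws, scale="raw") -> PosteriorSummary:
    """Convenience wrapper building a :class:`PosteriorSummary`."""
    return PosteriorSummary(name=name, draws=draws, scale=scale)
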