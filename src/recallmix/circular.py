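"""Circular geometry and von Mises utilities for color-wheel error data.

All public APIs work in degrees, matching how continuous-report color
judgments are reported: angles live on ``[0, 360)``, signed errors on
``(-180, 180]``, and the fidelity of a memory trace is expressed either as
the von Mises concentration ``kappa`` (dimensionless, >= 0) or as the
circular standard deviation ``sigma`` in degrees via

    sigma = sqrt(-2 * ln(I1(kappa) / I0(kappa)))    (radians -> degrees)

Radians are used only internally.  The signed-error convention is
``response - studied`` wrapped to ``(-180, 180]``; every model downstream is
symmetric in the error, so the choice of sign is inconsequential but fixed.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from scipy.optimize import brentq

__all__ = [
    "KAPPA_MAX",
    "wrap_angle",
    "signed_error",
    "absolute_error",
    "bessel_ratio",
    "kappa_to_sigma",
    "sigma_to_kappa",
    "vm_density",
    "sample_von_mises",
    "circular_sd_deg",
]

#: Concentrations are capped here when inverting sigma -> kappa near
#: sigma -> 0 (kappa = 500 corresponds to sigma ~ 2.6 degrees); the
#: exponentially scaled Bessel ratio stays finite well beyond this.
KAPPA_MAX = 500.0


def _check_finite(x, name: str):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return x


def wrap_angle(angle_deg):
    """Wrap arbitrary angles in degrees onto ``[0, 360)``."""
    angle_deg = _check_finite(angle_deg, "angle_deg")
    return np.mod(angle_deg, 360.0)


def signed_error(studied_deg, response_deg):
    """Signed angular error ``response - studied`` wrapped to ``(-180, 180]``.

    0 means a perfect color match; +180 and -180 coincide (opposite color)
    and are reported as +180.
    """
    studied_deg = _check_finite(studied_deg, "studied_deg")
    response_deg = _check_finite(response_deg, "response_deg")
    diff = np.mod(np.asarray(response_deg, float) - studied_deg, 360.0)
    # map (180, 360) -> (-180, 0); leave 180 itself at +180
    err = np.where(diff > 180.0, diff - 360.0, diff)
    return err if err.ndim else float(err)


def absolute_error(studied_deg, response_deg):
    """Absolute angular distance in degrees, in ``[0, 180]``.

    0 is a perfect match, 180 the diametrically opposite color, and 90 the
    expected error under uniform guessing.
    """
    err = np.abs(signed_error(studied_deg, response_deg))
    return err if np.ndim(err) else float(err)


def bessel_ratio(kappa):
    """``I1(kappa) / I0(kappa)``, stable for large kappa via scaled Bessels."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    return special.i1e(kappa) / special.i0e(kappa)


def kappa_to_sigma(kappa):
    """Circular standard deviation (degrees) of a von Mises with given kappa.

    Strictly decreasing in kappa; ``kappa = 0`` maps to ``inf`` (the uniform
    limit has no finite circular SD under this definition).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    r = bessel_ratio(kappa)
    with np.errstate(divide="ignore"):
        sigma_rad = np.sqrt(-2.0 * np.log(r))
    out = np.degrees(sigma_rad)
    out = np.where(kappa == 0, np.inf, out)
    return out if out.ndim else float(out)


def sigma_to_kappa(sigma_deg):
    """Invert :func:`kappa_to_sigma` numerically (relative tolerance ~1e-12).

    Concentrations are capped at :data:`KAPPA_MAX` for very small sigma.
    """
    sigma_deg = np.asarray(sigma_deg, dtype=float)
    if np.any(sigma_deg <= 0):
        raise ValueError("sigma_deg must be > 0")

    def _invert(s):
        if s <= kappa_to_sigma(KAPPA_MAX):
            return KAPPA_MAX
        lo = 1e-10
        if s >= kappa_to_sigma(lo):
            return lo
        return brentq(lambda k: kappa_to_sigma(k) - s, lo, KAPPA_MAX,
                      xtol=1e-12, rtol=1e-14)

    out = np.vectorize(_invert, otypes=[float])(sigma_deg)
    return out if out.ndim else float(out)


def vm_density(error_deg, kappa):
    """von Mises density per *degree*, centred at zero error.

    ``exp(kappa * cos(e)) / (360 * I0(kappa))`` with e in radians inside the
    cosine; integrates to 1 over ``(-180, 180]``.  ``kappa = 0`` gives the
    uniform density 1/360.
    """
    error_deg = np.asarray(error_deg, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    c = np.cos(np.radians(error_deg))
    # log I0(k) = log(i0e(k)) + k keeps large kappa finite
    log_dens = kappa * c - (np.log(special.i0e(kappa)) + kappa) - np.log(360.0)
    out = np.exp(log_dens)
    return out if out.ndim else float(out)


def sample_von_mises(kappa, n, rng):
    """Draw ``n`` signed errors (degrees) from a zero-mean von Mises.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    ``kappa = 0`` falls back to uniform draws on ``(-180, 180]``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n == 0:
        return np.empty(0)
    if np.ndim(kappa) == 0 and kappa == 0:
        return 180.0 - rng.uniform(0.0, 360.0, size=n)
    draws_rad = stats.vonmises.rvs(kappa, size=n, random_state=rng)
    return np.degrees(draws_rad)


def circular_sd_deg(errors_deg):
    """Empirical circular standard deviation (degrees) of signed errors."""
    e = np.radians(np.asarray(errors_deg, dtype=float))
    r = np.hypot(np.mean(np.sin(e)), np.mean(np.cos(e)))
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))
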