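"""Analytical NMR lineshapes.

All absorption shapes are unit height at their center.  The Gaussian and
Lorentzian components share the same half width at half maximum (HWHM)
``gamma``, which ties the Gaussian standard deviation to
``sigma = gamma / sqrt(2 ln 2)``.  The pseudo-Voigt profile is the convex
mixture of the two and approximates the Voigt convolution profile that
real peaks exhibit under imperfect shimming.

Dispersion counterparts (the Hilbert transforms of the absorption shapes)
are needed to emulate phase distortion: a mis-phased peak is
``cos(phi) * absorption + sin(phi) * dispersion``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import dawsn

_SQRT_2LN2 = np.sqrt(2.0 * np.log(2.0))


def sigma_from_gamma(gamma: float) -> float:
    """Gaussian standard deviation with the same HWHM as a Lorentzian of HWHM ``gamma``."""
    return gamma / _SQRT_2LN2


def lorentzian(offset_hz, gamma: float):
    """Unit-height Lorentzian absorption: ``gamma^2 / (x^2 + gamma^2)``."""
    x = np.asarray(offset_hz, dtype=float)
    return gamma * gamma / (x * x + gamma * gamma)


def gaussian(offset_hz, gamma: float):
    """Unit-height Gaussian absorption with HWHM ``gamma``."""
    x = np.asarray(offset_hz, dtype=float)
    s = sigma_from_gamma(gamma)
    return np.exp(-0.5 * (x / s) ** 2)


def lorentzian_dispersion(offset_hz, gamma: float):
    """Dispersion partner of the unit-height Lorentzian: ``x*gamma / (x^2 + gamma^2)``.

    Antisymmetric, zero at the peak center, extrema +-0.5 at ``x = +-gamma``.
    """
    x = np.asarray(offset_hz, dtype=float)
    return x * gamma / (x * x + gamma * gamma)


def gaussian_dispersion(offset_hz, gamma: float):
    """Dispersion partner of the unit-height Gaussian.

    The Hilbert transform of ``exp(-t^2)`` is ``(2/sqrt(pi)) * dawsn(t)``;
    rescaling to HWHM ``gamma`` gives the closed form used here.
    """
    x = np.asarray(offset_hz, dtype=float)
    s = sigma_from_gamma(gamma)
    return (2.0 / np.sqrt(np.pi)) * dawsn(x / (s * np.sqrt(2.0)))


def pseudo_voigt(offset_hz, gamma: float, ls_mix: float):
    """Pseudo-Voigt absorption: ``ls_mix * G + (1 - ls_mix) * L``.

    Parameters
    ----------
    offset_hz
        Frequency offset from the peak center, Hz (scalar or array).
    gamma
        Lorentzian HWHM in Hz; must be positive.  The Gaussian component
        uses the same HWHM.
    ls_mix
        Mixing weight in [0, 1]; 0 is the pure Lorentzian limit, 1 the
        pure Gaussian limit.

    Returns
    -------
    Unit-height intensity, in (0, 1]; exactly 0.5 at ``offset = +-gamma``
    for every mixing weight because both components share the HWHM.
    """
    _check_params(gamma, ls_mix)
    return ls_mix * gaussian(offset_hz, gamma) + (1.0 - ls_mix) * lorentzian(offset_hz, gamma)


def pseudo_voigt_dispersion(offset_hz, gamma: float, ls_mix: float):
    """Dispersion partner of :func:`pseudo_voigt` (same mixing weight)."""
    _check_params(gamma, ls_mix)
    return ls_mix * gaussian_dispersion(offset_hz, gamma) + (1.0 - ls_mix) * lorentzian_dispersion(
        offset_hz, gamma
    )


def _check_params(gamma: float, ls_mix: float) -> None:
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma!r}")
    if not 0.0 <= ls_mix <= 1.0:
        raise ValueError(f"ls_mix must lie in [0, 1], got {ls_mix!r}")
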