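"""Closed-form hard-core thermodynamics used as ground truth.

nu_inf = rho k_B T kappa_T is the thermodynamic-limit relative number
fluctuation; it equals the reciprocal of d(beta p)/d rho.  All derivatives
are hand-differentiated closed forms (no finite differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidStateError, ParameterError, UnsupportedModelError
from .rdf_models import FluidSpec

__all__ = [
    "CompressibilityResult",
    "tonks_kappa",
    "tonks_npt_moments",
    "kappa_from_npt_moments",
    "carnahan_starling_nu",
    "py_compressibility_nu",
]


@dataclass(frozen=True)
class CompressibilityResult:
    """Isothermal compressibility and the equivalent relative fluctuation."""

    kappa_T: float
    nu_inf: float
    route: str


def tonks_kappa(spec: FluidSpec) -> CompressibilityResult:
    """Exact Tonks-fluid compressibility, kappa_T = beta (1 - rho sigma)^2 / rho.

    Follows from the exact equation of state beta p = rho/(1 - rho sigma);
    strictly size-independent.  nu_inf = (1 - rho sigma)^2.
    """
    if spec.dim != 1:
        raise UnsupportedModelError("tonks_kappa requires dim == 1")
    t = spec.rho * spec.sigma
    if not 0.0 < t < 1.0:
        raise InvalidStateError(f"rho*sigma = {t:g} outside (0, 1)")
    nu = (1.0 - t) ** 2
    return CompressibilityResult(kappa_T=spec.beta * nu / spec.rho, nu_inf=nu, route="tonks")


def tonks_npt_moments(N: int, betap: float, sigma: float) -> tuple[float, float]:
    """Mean and variance of the system length of N hard rods at fixed pressure.

    L - N sigma is the N-fold convolution of iid exponential gaps of rate
    beta p, i.e. gamma(N):  <L> = N sigma + N/(beta p),  Var L = N/(beta p)^2.
    Valid for any N >= 1.
    """
    if N < 1:
        raise ParameterError(f"N must be >= 1, got {N}")
    if betap <= 0:
        raise ParameterError(f"beta*p must be positive, got {betap}")
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    mean = N * sigma + N / betap
    var = N / betap**2
    return mean, var


def kappa_from_npt_moments(N: int, betap: float, sigma: float, beta: float = 1.0) -> float:
    """kappa_T from the isobaric length fluctuations: beta Var(L)/<L>.

    Algebraically identical, for every N, to the thermodynamic closed form
    evaluated at the implied density rho = N/<L> -- the hallmark that
    isobaric hypervolume fluctuations give the size-independent kappa_T.
    """
    mean, var = tonks_npt_moments(N, betap, sigma)
    return beta * var / mean


def carnahan_starling_nu(spec: FluidSpec) -> CompressibilityResult:
    """Carnahan-Starling compressibility route for 3D hard spheres.

    Z = (1 + eta + eta^2 - eta^3)/(1 - eta)^3, beta p = rho Z, and the
    analytic derivative gives
    d(beta p)/d rho = (1 + 4 eta + 4 eta^2 - 4 eta^3 + eta^4)/(1 - eta)^4,
    whose reciprocal is nu_inf.
    """
    if spec.dim != 3:
        raise UnsupportedModelError("carnahan_starling_nu requires dim == 3")
    eta = spec.eta
    if not 0.0 < eta < 0.64:
        raise InvalidStateError(f"eta = {eta:g} outside the CS validity range (0, 0.64)")
    dbp = (1.0 + 4.0 * eta + 4.0 * eta**2 - 4.0 * eta**3 + eta**4) / (1.0 - eta) ** 4
    nu = 1.0 / dbp
    return CompressibilityResult(
        kappa_T=spec.beta * nu / spec.rho, nu_inf=nu, route="carnahan-starling"
    )


def carnahan_starling_betap(rho: float, sigma: float = 1.0) -> float:
    """beta p of the Carnahan-Starling equation of state (for self-checks)."""
    eta = math.pi * rho * sigma**3 / 6.0
    return rho * (1.0 + eta + eta**2 - eta**3) / (1.0 - eta) ** 3


def py_compressibility_nu(spec: FluidSpec) -> CompressibilityResult:
    """Percus-Yevick compressibility-route closed form,
    nu_inf = (1 - eta)^4/(1 + 2 eta)^2 (the zero-wavevector structure factor
    of the Wertheim solution; oracle for the fitted intercepts)."""
    if spec.dim != 3:
        raise UnsupportedModelError("py_compressibility_nu requires dim == 3")
    eta = spec.eta
    if not 0.0 < eta < 0.74:
        raise InvalidStateError(f"eta = {eta:g} outside (0, 0.74)")
    nu = (1.0 - eta) ** 4 / (1.0 + 2.0 * eta) ** 2
    return CompressibilityResult(
        kappa_T=spec.beta * nu / spec.rho, nu_inf=nu, route="py-compressibility"
    )
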