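"""Finite-volume Kirkwood-Buff machinery.

The relative particle-number fluctuation of an open subvolume of linear size
L (segment length in 1D, sphere diameter in 3D) follows from the pair
structure through a geometric weight function w(r; L):

    nu(L)  = 1 + rho * int_0^L w(r) (g(r) - 1) dr          (point particles)
    nu~(L) =     rho * int_0^L w(r) (g~(r) - 1) dr          (modified RDF)

The +1 compensates the diagonal terms omitted from g; with the modified RDF
the diagonal is inside g~, so it is absent.  The "running" KBI replaces w by
2 (1D) or 4 pi r^2 (3D) -- the naive truncation, kept as a diagnostic: it
oscillates, turns negative, and diverges for solids.

In the thermodynamic limit nu(inf) = rho k_B T kappa_T; the 1/L approach to
that limit is quantified by an ordinary least-squares fit
nu(L) = nu(inf) + C/L over a large-L window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import CoverageError, FitError, ParameterError
from .excluded_volume import JUMP_THRESHOLD
from .rdf_models import FluidSpec, ShellRDF, TabulatedRDF

__all__ = [
    "FluctuationCurve",
    "AsymptoteFit",
    "weight_function",
    "nu_curve",
    "running_kbi_curve",
    "shell_nu_curve",
    "shell_running_kbi_curve",
    "fit_asymptote",
    "default_L_grid",
]


def weight_function(r, L: float, dim: int):
    """Geometric weight w(r; L) of the pair-distance distribution in V.

    1D segment of length L: w = 2 (1 - r/L).
    3D sphere of diameter L: w = 4 pi r^2 (1 - 1.5 x + 0.5 x^3), x = r/L.
    int_0^L w dr equals the subvolume hypervolume (L, resp. pi L^3/6).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > L * (1 + 1e-12)):
        raise ParameterError("weight_function requires 0 <= r <= L")
    x = np.clip(r / L, 0.0, 1.0)
    if dim == 1:
        return 2.0 * (1.0 - x)
    if dim == 3:
        return 4.0 * math.pi * r**2 * (1.0 - 1.5 * x + 0.5 * x**3)
    raise ParameterError(f"dim must be 1 or 3, got {dim}")


def subvolume(L: float, dim: int) -> float:
    """Hypervolume of the subvolume of linear size L."""
    return L if dim == 1 else math.pi * L**3 / 6.0


@dataclass
class FluctuationCurve:
    """nu (or nu~) as a function of subvolume size, with method metadata."""

    L_grid: np.ndarray
    nu_values: np.ndarray
    method: str  # "finite_volume" | "running_kbi"
    modified: bool
    spec: Optional[FluidSpec] = None
    profile_diameter: Optional[float] = None

    def __post_init__(self) -> None:
        self.L_grid = np.asarray(self.L_grid, dtype=float)
        self.nu_values = np.asarray(self.nu_values, dtype=float)

    def to_table(self, path) -> None:
        lines = [f"# method = {self.method}", f"# modified = {str(self.modified).lower()}"]
        if self.spec is not None:
            lines += [
                f"# rho = {self.spec.rho!r}",
                f"# sigma = {self.spec.sigma!r}",
                f"# dim = {self.spec.dim}",
            ]
        if self.profile_diameter is not None:
            lines.append(f"# a = {self.profile_diameter!r}")
        lines.append("# columns = L nu")
        with Path(path).open("w") as fh:
            fh.write("\n".join(lines) + "\n")
            np.savetxt(fh, np.column_stack([self.L_grid, self.nu_values]), fmt="%.17g")


@dataclass
class AsymptoteFit:
    """Result of the linear fit nu(L) = nu(inf) + C/L."""

    nu_inf: float
    slope: float
    fit_range: tuple[float, float]
    residual_norm: float
    n_points: int
    nu_inf_stability: float  # |change of nu_inf| under a 20% perturbed range


def default_L_grid(rdf: TabulatedRDF, L_min: Optional[float] = None, dL: Optional[float] = None) -> np.ndarray:
    """L grid from the smallest physical size to 0.8 r_max (default step 0.1 sigma)."""
    sigma = rdf.spec.sigma
    if L_min is None:
        L_min = rdf.profile_diameter if rdf.includes_diagonal and rdf.profile_diameter else sigma
    if dL is None:
        dL = 0.1 * sigma
    L_max = 0.8 * rdf.r_max
    n = int(math.floor((L_max - L_min) / dL + 1e-9))
    return L_min + dL * np.arange(n + 1)


def _jump_index(g: np.ndarray) -> Optional[int]:
    d = np.abs(np.diff(g))
    i = int(np.argmax(d))
    return i + 1 if d[i] > JUMP_THRESHOLD else None


def _curve(rdf: TabulatedRDF, L_grid, running: bool) -> FluctuationCurve:
    L_grid = np.atleast_1d(np.asarray(L_grid, dtype=float))
    r = rdf.r_grid
    g = rdf.g_values
    spec = rdf.spec
    if r[0] != 0.0:
        raise CoverageError("RDF grid must start at r = 0 for fluctuation integrals")
    if L_grid.max() > rdf.r_max * (1 + 1e-12):
        raise CoverageError(
            f"L = {L_grid.max():g} exceeds the RDF coverage r_max = {rdf.r_max:g} "
            f"by {L_grid.max() - rdf.r_max:g}"
        )
    jump = _jump_index(g)
    h = g - 1.0
    nu = np.empty_like(L_grid)
    for idx, L in enumerate(L_grid):
        iL = int(np.searchsorted(r, L, side="right")) - 1
        rr = r[: iL + 1]
        if running:
            w = 2.0 * np.ones_like(rr) if spec.dim == 1 else 4.0 * math.pi * rr**2
        else:
            w = weight_function(rr, L, spec.dim)
        f = w * h[: iL + 1]
        integral = np.trapezoid(f, rr)
        if r[iL] < L:  # partial last cell up to L (w(L)=0 for finite-volume)
            gL = float(np.interp(L, r, g))
            if running:
                wL = 2.0 if spec.dim == 1 else 4.0 * math.pi * L**2
            else:
                wL = 0.0
            integral += 0.5 * (f[-1] + wL * (gL - 1.0)) * (L - r[iL])
        if jump is not None and 1 <= jump <= iL:
            # the stored value at the jump is the right limit; the cell below
            # it must use the left limit (previous sample) instead
            if running:
                wj = 2.0 if spec.dim == 1 else 4.0 * math.pi * r[jump] ** 2
            else:
                wj = float(weight_function(r[jump], L, spec.dim))
            integral += 0.5 * (r[jump] - r[jump - 1]) * wj * (g[jump - 1] - g[jump])
        nu[idx] = spec.rho * integral
    if not rdf.includes_diagonal:
        nu += 1.0
    return FluctuationCurve(
        L_grid,
        nu,
        method="running_kbi" if running else "finite_volume",
        modified=rdf.includes_diagonal,
        spec=spec,
        profile_diameter=rdf.profile_diameter,
    )


def nu_curve(rdf: TabulatedRDF, L_grid) -> FluctuationCurve:
    """Finite-volume fluctuation curve nu(L) (or nu~(L) for a modified RDF).

    Trapezoidal quadrature on the stored grid; a hard-core contact
    discontinuity in g is integrated with one-sided limits so the step
    contributes no O(dr) error.
    """
    return _curve(rdf, L_grid, running=False)


def running_kbi_curve(rdf: TabulatedRDF, L_grid) -> FluctuationCurve:
    """Running-KBI diagnostic: the truncated infinite-volume integral."""
    return _curve(rdf, L_grid, running=True)


def shell_nu_curve(shells: ShellRDF, L_grid) -> FluctuationCurve:
    """Finite-volume nu(L) of a delta-comb (crystal) RDF, analytic in the shells:
    nu(L) = 1 + sum_{d_m <= L} c_m w(d_m; L)/(4 pi d_m^2) - rho pi L^3/6."""
    L_grid = np.atleast_1d(np.asarray(L_grid, dtype=float))
    if L_grid.max() > shells.r_max:
        raise CoverageError("L exceeds the enumerated shell range")
    rho = shells.density
    nu = np.empty_like(L_grid)
    d, c = shells.shell_distances, shells.shell_counts
    for i, L in enumerate(L_grid):
        m = d <= L
        nu[i] = 1.0 + np.sum(
            c[m] * weight_function(d[m], L, 3) / (4.0 * math.pi * d[m] ** 2)
        ) - rho * subvolume(L, 3)
    return FluctuationCurve(L_grid, nu, method="finite_volume", modified=False)


def shell_running_kbi_curve(shells: ShellRDF, L_grid) -> FluctuationCurve:
    """Running KBI of a crystal RDF: 1 + sum_{d<=L} c_m - rho (4/3) pi L^3."""
    L_grid = np.atleast_1d(np.asarray(L_grid, dtype=float))
    if L_grid.max() > shells.r_max:
        raise CoverageError("L exceeds the enumerated shell range")
    rho = shells.density
    nu = np.array(
        [
            1.0 + shells.cumulative_count(L) - rho * 4.0 * math.pi * L**3 / 3.0
            for L in L_grid
        ]
    )
    return FluctuationCurve(L_grid, nu, method="running_kbi", modified=False)


def fit_asymptote(
    curve: FluctuationCurve, fit_range: Optional[tuple[float, float]] = None
) -> AsymptoteFit:
    """OLS fit of nu against 1/L over fit_range (default [10 sigma, L_max]).

    Also refits over a 20%-shortened range and reports the intercept shift
    as a stability measure.
    """
    L = curve.L_grid
    nu = curve.nu_values
    if fit_range is None:
        sigma = curve.spec.sigma if curve.spec is not None else 1.0
        fit_range = (10.0 * sigma, float(L.max()))
    lo, hi = fit_range

    def _ols(lo_, hi_):
        m = (L >= lo_) & (L <= hi_)
        if m.sum() < 10:
            raise FitError(
                f"fit range [{lo_:g}, {hi_:g}] contains only {int(m.sum())} points (need >= 10)"
            )
        A = np.column_stack([np.ones(m.sum()), 1.0 / L[m]])
        coef, res, *_ = np.linalg.lstsq(A, nu[m], rcond=None)
        resid = nu[m] - A @ coef
        return coef, float(np.sqrt(np.sum(resid**2))), int(m.sum())

    coef, rnorm, npts = _ols(lo, hi)
    try:
        coef_p, _, _ = _ols(lo + 0.2 * (hi - lo), hi)
        stability = abs(coef_p[0] - coef[0])
    except FitError:
        stability = math.nan
    return AsymptoteFit(
        nu_inf=float(coef[0]),
        slope=float(coef[1]),
        fit_range=(float(lo), float(hi)),
        residual_norm=rnorm,
        n_points=npts,
        nu_inf_stability=float(stability),
    )
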