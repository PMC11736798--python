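"""Radial distribution functions of hard-core reference systems.

Analytic models:

* the 1D hard-rod (Tonks) fluid, whose grand-canonical pair correlation is an
  exact sum of shifted gamma densities (nearest-neighbour distributions),
* the 3D hard-sphere fluid in the Percus-Yevick approximation (Wertheim's
  analytic Laplace-space solution, inverted shell by shell),
* the hard-sphere FCC crystal at close packing, represented by its exact
  coordination shells,

plus a plain-text tabulated-RDF format for interchange.

All lengths are in units of the hard-core diameter sigma unless a FluidSpec
says otherwise; hard-core systems are athermal so beta only sets the unit of
pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from .errors import (
    InvalidStateError,
    ParameterError,
    RDFFormatError,
    TruncationError,
    UnsupportedModelError,
)
from ._wertheim import py_rdf_values

__all__ = [
    "FluidSpec",
    "TabulatedRDF",
    "ShellRDF",
    "ETA_FCC",
    "tonks_pressure",
    "tonks_nn_distribution",
    "tonks_rdf",
    "py_rdf",
    "fcc_shells",
    "default_r_grid",
    "read_rdf",
    "write_rdf",
]

#: close-packing fraction of the FCC crystal, pi/sqrt(18)
ETA_FCC = math.pi / math.sqrt(18.0)

#: hard cap on the number of nearest-neighbour terms in the Tonks sum
TONKS_N_CAP = 100_000


@dataclass(frozen=True)
class FluidSpec:
    """Thermodynamic state of a homogeneous hard-core fluid.

    Parameters
    ----------
    rho : float
        Number density (particles per hypervolume, in sigma units).
    sigma : float
        Hard-core diameter.
    dim : int
        Spatial dimension, 1 or 3.
    beta : float
        Inverse temperature. Hard-core thermodynamics is athermal, so beta
        only fixes the pressure unit; default 1.
    """

    rho: float
    sigma: float = 1.0
    dim: int = 3
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise InvalidStateError(f"rho must be positive, got {self.rho}")
        if self.sigma <= 0:
            raise InvalidStateError(f"sigma must be positive, got {self.sigma}")
        if self.dim not in (1, 3):
            raise UnsupportedModelError(f"dim must be 1 or 3, got {self.dim}")
        if self.beta <= 0:
            raise InvalidStateError(f"beta must be positive, got {self.beta}")
        if self.dim == 1 and self.rho * self.sigma >= 1.0:
            raise InvalidStateError(
                f"1D filling rho*sigma = {self.rho * self.sigma:g} >= 1 (close packing)"
            )
        # equality allowed: the FCC crystal sits exactly at close packing
        if self.dim == 3 and self.eta > ETA_FCC * (1 + 1e-12):
            raise InvalidStateError(
                f"3D packing fraction eta = {self.eta:g} > pi/sqrt(18) (close packing)"
            )

    @property
    def eta(self) -> float:
        """Filling fraction: rho*sigma in 1D, pi*rho*sigma^3/6 in 3D."""
        if self.dim == 1:
            return self.rho * self.sigma
        return math.pi * self.rho * self.sigma**3 / 6.0


@dataclass
class TabulatedRDF:
    """A pair correlation function g(r) sampled on a uniform grid.

    ``includes_diagonal`` is True only for excluded-volume-modified RDFs,
    where the self (i = j) term chi(r)/rho of the two-particle density is
    folded into g; ``profile_diameter`` then records the particle-profile
    diameter a used in the convolution.
    """

    r_grid: np.ndarray
    g_values: np.ndarray
    spec: FluidSpec
    includes_diagonal: bool = False
    profile_diameter: Optional[float] = None
    diagonal_component: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.g_values = np.asarray(self.g_values, dtype=float)
        if self.r_grid.ndim != 1 or self.r_grid.shape != self.g_values.shape:
            raise RDFFormatError("r_grid and g_values must be matching 1D arrays")
        if np.any(np.diff(self.r_grid) <= 0):
            raise RDFFormatError("r_grid must be strictly increasing")
        if np.any(self.g_values < -1e-12):
            raise RDFFormatError("g(r) must be non-negative")

    @property
    def r_max(self) -> float:
        return float(self.r_grid[-1])

    def __call__(self, r):
        """Interpolate g at r; 0 below the grid, 1 above it (fluid tail)."""
        return np.interp(r, self.r_grid, self.g_values, left=0.0, right=1.0)


@dataclass
class ShellRDF:
    """Delta-function RDF of a perfect crystal, stored as coordination shells.

    ``shell_distances[m]`` is the m-th neighbour distance and
    ``shell_counts[m]`` the number of lattice sites at that distance.
    g(r) = sum_m counts[m] delta(r - d_m) / (4 pi rho d_m^2).
    """

    shell_distances: np.ndarray
    shell_counts: np.ndarray
    density: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        self.shell_distances = np.asarray(self.shell_distances, dtype=float)
        self.shell_counts = np.asarray(self.shell_counts, dtype=float)
        if np.any(np.diff(self.shell_distances) <= 0):
            raise RDFFormatError("shell distances must be strictly increasing")
        if np.any(self.shell_counts <= 0):
            raise RDFFormatError("shell counts must be positive")

    @property
    def r_max(self) -> float:
        return float(self.shell_distances[-1])

    def cumulative_count(self, r: float) -> float:
        """Number of neighbours within distance r of a lattice site."""
        return float(self.shell_counts[self.shell_distances <= r].sum())


# ----------------------------------------------------------------------------
# 1D Tonks fluid
# ----------------------------------------------------------------------------

def tonks_pressure(spec: FluidSpec) -> float:
    """beta*p of the Tonks fluid: rho/(1 - rho*sigma)."""
    _require_1d(spec)
    return spec.rho / (1.0 - spec.rho * spec.sigma)


def _require_1d(spec: FluidSpec) -> None:
    if spec.dim != 1:
        raise UnsupportedModelError("Tonks model is one-dimensional; spec.dim must be 1")
    if spec.rho * spec.sigma >= 1.0:
        raise InvalidStateError("rho*sigma >= 1: above hard-rod close packing")


def tonks_nn_distribution(n: int, spec: FluidSpec, r) -> np.ndarray:
    """Distribution p_n(r) of the distance to the n-th neighbour on one side.

    In the Tonks fluid the gaps between consecutive rods are iid exponential
    with rate beta*p = rho/(1-rho*sigma), so r - n*sigma is gamma(n) with that
    rate: p_n(r) = bp*(bp*(r-n*sigma))^(n-1)/(n-1)! * exp(-bp*(r-n*sigma))
    for r >= n*sigma and 0 otherwise.
    """
    _require_1d(spec)
    if n < 1:
        raise ParameterError(f"neighbour order n must be >= 1, got {n}")
    bp = tonks_pressure(spec)
    return stats.gamma.pdf(np.asarray(r, dtype=float), a=n, loc=n * spec.sigma, scale=1.0 / bp)


def default_r_grid(spec: FluidSpec, r_max: Optional[float] = None, dr: Optional[float] = None) -> np.ndarray:
    """Uniform grid from 0 to r_max; defaults dr = 1e-3 sigma,
    r_max = 50 sigma (1D) or 30 sigma (3D)."""
    if r_max is None:
        r_max = (50.0 if spec.dim == 1 else 30.0) * spec.sigma
    if dr is None:
        dr = 1e-3 * spec.sigma
    n = int(round(r_max / dr))
    return np.linspace(0.0, n * dr, n + 1)


def tonks_rdf(spec: FluidSpec, r_grid: Optional[np.ndarray] = None) -> TabulatedRDF:
    """Exact grand-canonical RDF of the Tonks fluid.

    g(r) = (1/rho) * sum_n p_n(r). Each p_n vanishes identically below
    n*sigma, so summing all n with n*sigma <= r_max (plus a small buffer)
    leaves no truncation error on the grid.
    """
    _require_1d(spec)
    if r_grid is None:
        r_grid = default_r_grid(spec)
    r_grid = np.asarray(r_grid, dtype=float)
    r_max = float(r_grid[-1])
    bp = tonks_pressure(spec)
    n_max = int(math.ceil((r_max + 10.0 / bp) / spec.sigma)) + 1
    if n_max > TONKS_N_CAP:
        raise TruncationError(
            f"Tonks sum needs {n_max} neighbour terms for r_max={r_max:g} "
            f"(cap {TONKS_N_CAP}); reduce r_max or raise the cap"
        )
    g = np.zeros_like(r_grid)
    for n in range(1, n_max + 1):
        if n * spec.sigma > r_max:
            break
        g += stats.gamma.pdf(r_grid, a=n, loc=n * spec.sigma, scale=1.0 / bp)
    g /= spec.rho
    return TabulatedRDF(r_grid, g, spec)


# ----------------------------------------------------------------------------
# 3D Percus-Yevick hard-sphere fluid
# ----------------------------------------------------------------------------

def py_rdf(spec: FluidSpec, r_grid: Optional[np.ndarray] = None) -> TabulatedRDF:
    """Hard-sphere RDF in the Percus-Yevick approximation (Wertheim solution).

    Evaluated from the analytic Laplace-space solution: exact residue (shell)
    expansion near contact, exact pole expansion of the same transform at
    larger r. See the methods note for the numerics.
    """
    if spec.dim != 3:
        raise UnsupportedModelError("py_rdf is the 3D Percus-Yevick solution; spec.dim must be 3")
    if spec.eta >= ETA_FCC:
        raise InvalidStateError(f"eta = {spec.eta:g} at or above close packing")
    if r_grid is None:
        r_grid = default_r_grid(spec)
    r_grid = np.asarray(r_grid, dtype=float)
    g = py_rdf_values(spec.eta, r_grid / spec.sigma)
    return TabulatedRDF(r_grid, g, spec)


# ----------------------------------------------------------------------------
# FCC hard-sphere solid
# ----------------------------------------------------------------------------

def fcc_shells(sigma: float = 1.0, r_max: float = 12.0) -> ShellRDF:
    """Coordination shells of the close-packed FCC crystal.

    Nearest-neighbour distance equals sigma (touching spheres), so the cubic
    lattice constant is sigma*sqrt(2) and the density rho = sqrt(2)/sigma^3.
    Shells are enumerated exactly from the integer FCC lattice
    {(i,j,k): i+j+k even} scaled by sigma/sqrt(2).
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    if r_max < 2.0 * sigma:
        raise ParameterError("r_max must be at least 2*sigma")
    # d^2 = (sigma^2/2) * (i^2+j^2+k^2), i+j+k even
    m_max = int(math.ceil(2.0 * (r_max / sigma) ** 2))
    n_idx = int(math.ceil(math.sqrt(m_max))) + 1
    counts: dict[int, int] = {}
    for i in range(-n_idx, n_idx + 1):
        for j in range(-n_idx, n_idx + 1):
            for k in range(-n_idx, n_idx + 1):
                if (i + j + k) % 2 != 0 or (i == 0 and j == 0 and k == 0):
                    continue
                m = i * i + j * j + k * k
                if m <= m_max:
                    counts[m] = counts.get(m, 0) + 1
    ms = sorted(counts)
    d = sigma * np.sqrt(np.array(ms, dtype=float) / 2.0)
    c = np.array([counts[m] for m in ms], dtype=float)
    keep = d <= r_max + 1e-12
    return ShellRDF(d[keep], c[keep], density=math.sqrt(2.0) / sigma**3, sigma=sigma)


# ----------------------------------------------------------------------------
# Tabulated-RDF text I/O
# ----------------------------------------------------------------------------

_REQUIRED_KEYS = ("rho", "sigma", "dim")


def write_rdf(rdf: TabulatedRDF, path) -> None:
    """Write a tabulated RDF as whitespace-delimited text with '#' metadata.

    Modified RDFs gain ``modified = true``, an ``a`` key, and a third column
    holding the diagonal (self) component.
    """
    path = Path(path)
    lines = [
        f"# rho = {rdf.spec.rho!r}",
        f"# sigma = {rdf.spec.sigma!r}",
        f"# dim = {rdf.spec.dim}",
        f"# beta = {rdf.spec.beta!r}",
    ]
    cols = [rdf.r_grid, rdf.g_values]
    if rdf.includes_diagonal:
        lines.append("# modified = true")
        lines.append(f"# a = {rdf.profile_diameter!r}")
        diag = rdf.diagonal_component
        if diag is None:
            diag = np.zeros_like(rdf.r_grid)
        cols.append(diag)
    body = np.column_stack(cols)
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, body, fmt="%.17g")


def read_rdf(path) -> TabulatedRDF:
    """Read a tabulated RDF written by :func:`write_rdf` (round-trip exact)."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("#").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise RDFFormatError(f"{path}:{lineno}: non-numeric data {line!r}") from exc
    missing = [k for k in _REQUIRED_KEYS if k not in meta]
    if missing:
        raise RDFFormatError(
            f"{path}: missing required metadata keys: {', '.join(missing)} "
            f"(need '# key = value' lines for {', '.join(_REQUIRED_KEYS)})"
        )
    data = np.array(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise RDFFormatError(f"{path}: expected at least two numeric columns")
    r, g = data[:, 0], data[:, 1]
    bad = np.nonzero(np.diff(r) <= 0)[0]
    if bad.size:
        raise RDFFormatError(f"{path}: r grid not strictly increasing near data row {bad[0] + 2}")
    if np.any(g < 0):
        row = int(np.nonzero(g < 0)[0][0]) + 1
        raise RDFFormatError(f"{path}: negative g(r) at data row {row}")
    spec = FluidSpec(
        rho=float(meta["rho"]),
        sigma=float(meta["sigma"]),
        dim=int(meta["dim"]),
        beta=float(meta.get("beta", 1.0)),
    )
    modified = meta.get("modified", "false").lower() in ("true", "1", "yes")
    diag = data[:, 2] if (modified and data.shape[1] >= 3) else None
    return TabulatedRDF(
        r,
        g,
        spec,
        includes_diagonal=modified,
        profile_diameter=float(meta["a"]) if modified else None,
        diagonal_component=diag,
    )
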