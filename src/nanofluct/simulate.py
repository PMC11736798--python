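"""Monte-Carlo oracle for the 1D hard-rod fluid.

Canonical Metropolis sampling of N = round(rho L_box) rods in a periodic box,
with direct measurement of the RDF and of window number fluctuations.  The
window is placed uniformly at random; for L_w << L_box it is effectively an
open (grand-canonical) subvolume.

Two counting modes:

* ``discrete``  -- count rod centers inside the window (point particles);
* ``fractional`` -- each rod carries a uniform profile of length a, and a rod
  straddling the window boundary contributes its exact overlap fraction
  (interval intersection length / a), making the count continuous.

The fractional mode measures the excluded-volume-corrected fluctuations
directly, independently of any convolution code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import PackingError, ParameterError
from .rdf_models import FluidSpec, TabulatedRDF

__all__ = [
    "Configuration1D",
    "WindowStats",
    "sample_tonks",
    "window_fluctuations",
    "rdf_histogram",
    "sphere_overlap_volume",
]


@dataclass
class Configuration1D:
    """Sorted hard-rod centers in a periodic box."""

    positions: np.ndarray
    sigma: float
    box_length: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)

    def gaps(self) -> np.ndarray:
        """Periodic nearest-neighbour surface-to-surface gaps (>= 0)."""
        x = self.positions
        d = np.diff(np.append(x, x[0] + self.box_length))
        return d - self.sigma


@dataclass
class WindowStats:
    """Window-counting fluctuation estimate with batch-means error bar."""

    window_size: float
    n_samples: int
    mean_count: float
    count_variance: float
    mode: str
    nu: float
    nu_se: float


def sample_tonks(
    spec: FluidSpec,
    L_box: float,
    n_sweeps: int,
    seed: int,
    equilibration: int = 1000,
    sample_every: int = 10,
    max_step: Optional[float] = None,
) -> list[Configuration1D]:
    """Metropolis single-particle-displacement sampling of the Tonks fluid.

    N = round(rho L_box) rods in a periodic box; one sweep = N attempted
    moves.  Internally the state is the gap vector (a displacement of rod i
    shifts gap i-1 up and gap i down; accepted iff both stay non-negative),
    which enforces the hard constraint exactly.  Configurations are recorded
    every ``sample_every`` sweeps after ``equilibration`` sweeps.
    """
    if spec.dim != 1:
        raise ParameterError("sample_tonks simulates the 1D hard-rod fluid")
    if L_box < 20.0 * spec.sigma:
        raise ParameterError("L_box must be at least 20 sigma")
    N = int(round(spec.rho * L_box))
    free = L_box - N * spec.sigma
    if N < 2 or free <= 0:
        raise PackingError(
            f"N = {N} rods of length {spec.sigma:g} do not fit a box of {L_box:g}"
        )
    rng = np.random.default_rng(seed)
    gaps = np.full(N, free / N)
    if max_step is None:
        # of the order of the mean free gap so dilute systems mix too
        max_step = max(0.5 * spec.sigma, free / N)
    configs: list[Configuration1D] = []
    for sweep in range(equilibration + n_sweeps):
        idx = rng.integers(0, N, size=N)
        dx = rng.uniform(-max_step, max_step, size=N)
        for i, d in zip(idx, dx):
            left = (i - 1) % N
            if gaps[left] + d >= 0.0 and gaps[i] - d >= 0.0:
                gaps[left] += d
                gaps[i] -= d
        if sweep >= equilibration and (sweep - equilibration) % sample_every == 0:
            x = spec.sigma * np.arange(N) + np.concatenate(([0.0], np.cumsum(gaps[:-1])))
            configs.append(Configuration1D(x, spec.sigma, L_box))
    return configs


def _window_counts(
    config: Configuration1D, starts: np.ndarray, L_w: float, mode: str, a: float
) -> np.ndarray:
    x = config.positions
    L = config.box_length
    counts = np.empty(starts.size)
    for j, w0 in enumerate(starts):
        y = np.mod(x - w0, L)
        if mode == "discrete":
            counts[j] = np.count_nonzero(y < L_w)
        else:
            lo, hi = y - a / 2.0, y + a / 2.0
            ov = np.clip(np.minimum(hi, L_w) - np.maximum(lo, 0.0), 0.0, a)
            # a rod near y ~ L wraps around and may re-enter the window at 0
            ov += np.clip(np.minimum(hi - L, L_w) - np.maximum(lo - L, 0.0), 0.0, a)
            counts[j] = ov.sum() / a
    return counts


def window_fluctuations(
    configs: Sequence[Configuration1D],
    L_w: float,
    mode: str = "discrete",
    a: Optional[float] = None,
    windows_per_config: int = 20,
    seed: int = 0,
    n_batches: int = 20,
) -> WindowStats:
    """Estimate nu = Var(N)/<N> from randomly placed windows.

    Windows are placed uniformly; the standard error of nu comes from batch
    means over ``n_batches`` contiguous blocks of configurations.
    """
    configs = list(configs)
    if not configs:
        raise ParameterError("empty configuration stream")
    box = configs[0].box_length
    if L_w > box / 4.0:
        raise ParameterError(
            f"window L_w = {L_w:g} exceeds L_box/4 = {box / 4:g} (decorrelation bound)"
        )
    if mode not in ("discrete", "fractional"):
        raise ParameterError(f"mode must be 'discrete' or 'fractional', got {mode!r}")
    if mode == "fractional":
        a = a if a is not None else configs[0].sigma
        if a <= 0:
            raise ParameterError("fractional counting needs a positive profile length a")
    else:
        a = 0.0
    rng = np.random.default_rng(seed)
    all_counts = []
    for cfg in configs:
        starts = rng.uniform(0.0, box, size=windows_per_config)
        all_counts.append(_window_counts(cfg, starts, L_w, mode, a))
    counts = np.concatenate(all_counts)
    mean = float(counts.mean())
    var = float(counts.var())
    nu = var / mean
    # batch means over configurations (windows within a config are correlated)
    nb = min(n_batches, len(configs))
    batches = np.array_split(np.arange(len(configs)), nb)
    nu_b = []
    for b in batches:
        c = np.concatenate([all_counts[i] for i in b])
        nu_b.append(c.var() / c.mean())
    nu_b = np.array(nu_b)
    se = float(nu_b.std(ddof=1) / math.sqrt(nb)) if nb > 1 else math.inf
    return WindowStats(
        window_size=L_w,
        n_samples=counts.size,
        mean_count=mean,
        count_variance=var,
        mode=mode,
        nu=nu,
        nu_se=se,
    )


def rdf_histogram(
    configs: Sequence[Configuration1D],
    bin_width: float = 0.01,
    r_max: Optional[float] = None,
) -> TabulatedRDF:
    """Pair-distance histogram estimate of g(r) with minimum-image distances."""
    configs = list(configs)
    if len(configs) < 100:
        raise ParameterError(f"need >= 100 decorrelated configurations, got {len(configs)}")
    box = configs[0].box_length
    sigma = configs[0].sigma
    if r_max is None:
        r_max = box / 2.0
    r_max = min(r_max, box / 2.0)
    nbins = int(r_max / bin_width)
    edges = bin_width * np.arange(nbins + 1)
    hist = np.zeros(nbins)
    n_total = 0
    for cfg in configs:
        x = cfg.positions
        d = np.abs(x[:, None] - x[None, :])
        d = np.minimum(d, box - d)
        iu = np.triu_indices(x.size, k=1)
        hist += np.histogram(d[iu], bins=edges)[0]
        n_total += x.size
    rho = n_total / (len(configs) * box)
    n_cfg = len(configs)
    N = n_total / n_cfg
    # ideal-gas expectation per bin: N(N-1) * bin_width / L_box unordered
    # pairs (the N-1 removes the leading canonical self-exclusion bias)
    g = hist * box / (n_cfg * N * (N - 1) * bin_width)
    centers = edges[:-1] + bin_width / 2.0
    spec = FluidSpec(rho=rho, sigma=sigma, dim=1)
    return TabulatedRDF(centers, g, spec)


def sphere_overlap_volume(R1: float, R2: float, d: float) -> float:
    """Overlap volume of spheres of radii R1, R2 at center distance d.

    Pure geometry helper for fractional counting of 3D particles in a
    spherical sampling volume.
    """
    if R1 < 0 or R2 < 0 or d < 0:
        raise ParameterError("radii and distance must be non-negative")
    if d >= R1 + R2:
        return 0.0
    if d <= abs(R1 - R2):
        r = min(R1, R2)
        return 4.0 * math.pi * r**3 / 3.0
    return (
        math.pi
        * (R1 + R2 - d) ** 2
        * (d**2 + 2.0 * d * (R1 + R2) - 3.0 * (R1 - R2) ** 2)
        / (12.0 * d)
    )
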