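# Methods

## Model and scope

The package computes relative particle-number fluctuations ν = ⟨δN²⟩/⟨N⟩ of
open subvolumes embedded in a homogeneous hard-core fluid (or crystal), and
from them the isothermal compressibility via ν(∞) = ρ k_B T κ_T. Everything
is athermal: β enters only as the pressure unit, and σ = 1 internally (all
lengths are stored in units of the hard-core diameter; `FluidSpec` carries
the scale).

Two counting conventions are implemented side by side:

* **point particles** — ν(L) = 1 + ρ∫₀ᴸ w(r)(g − 1)dr with the standard
  RDF; the +1 compensates the diagonal (i = j) terms omitted from g;
* **finite-size particles** — each particle carries a uniform profile of
  diameter a (a box in 1D, a ball in 3D); the full two-particle density
  (pair part ρ²g plus diagonal ρδ) is convolved with the profile-overlap
  kernel χ, giving g̃ = (χ ⊛ ρ²g)/ρ² + χ/ρ and
  ν̃(L) = ρ∫₀ᴸ w(r)(g̃ − 1)dr with no +1.

The weight w(r; L) is the pair-distance distribution of the subvolume:
2(1 − r/L) for a 1D segment, 4πr²(1 − 3x/2 + x³/2) for a 3D sphere of
diameter L; ∫₀ᴸ w dr equals the subvolume hypervolume exactly. The "running"
Kirkwood–Buff truncation (w → 2 or 4πr²) is provided only as a diagnostic:
it oscillates, goes negative for hard rods at high filling, and diverges for
crystals, all of which the tests assert.

Both conventions share the same L → ∞ limit for any a (convolution with a
normalized kernel preserves the integral of R − ρ²); the convolution removes
the leading 1/L surface term, which is what makes ν̃ usable at L ≈ σ.

## Kernels

χ is the self-convolution of the single-particle profile:

* 1D: triangle χ(r) = (1 − r/a)/a on r < a, peak 1/a;
* 3D: overlap volume of two balls of diameter a at distance r over V₀²,
  χ(r) = (1 − 3s/2 + s³/2)/V₀, s = r/a < 1, V₀ = πa³/6.

Both integrate to 1 over all space (asserted at 1e−10). In 3D the radial
convolution reduces to a line convolution: r(χ ⊛ f)(r) = ∫k(r − s) s f(s) ds
with k(t) = 2π∫_{|t|}^{a} uχ(u)du = (6/5a)(1 − 5s² + 5s³ − s⁵), f extended
evenly. For delta-comb (crystal) RDFs this sum is evaluated in closed form
shell by shell — no binning anywhere.

## Effective diameters

The "natural" profile is a = σ. At lower filling the modified curve retains
a negative 1/L term, removed by a reduced diameter chosen so that ν̃ is
size-independent (the physically required property, since κ_T of the
hard-rod fluid is exactly size-independent in the isobaric ensemble):

    a₁/σ = 1 − (1 − ρσ)³,        a₃/σ = 1 − exp(−5.6 ρσ³).

a₁ → 0 as ρ → 0 (point particles recovered, ideal-gas limit), a₁ → σ at
close packing, and 1 − a₁/σ = 0.8% at ρσ = 0.8. With a = a₁ the fitted
slope at ρσ = 0.2 collapses from −0.149 to −0.004 (97% suppression,
asserted). a₃ is an empirical fit on the same criterion for 3D; its printed
3-decimal values at ρ = 0.1…0.7 are frozen in the tests.

## Reference structures

* **Tonks fluid (1D, exact).** g(r) = ρ⁻¹Σₙ pₙ(r) where pₙ is the gamma
  density of rate βp = ρ/(1 − ρσ) shifted by nσ (the n-th-neighbour
  distance law). Terms with nσ > r_max vanish identically on the grid, so
  the sum is exact there; a cap guards absurd ranges. Contact value
  1/(1 − ρσ); correlations decay exponentially (≈2e−4 at 20σ for ρσ = 0.8,
  <1e−6 only beyond ~30σ — the tests assert the measured rates).
  The closed forms βp, κ_T = β(1 − ρσ)²/ρ, and the isobaric moments
  ⟨L⟩ = Nσ + N/βp, Var L = N/βp² (any N) are in `eos`; the moment route
  reproduces κ_T identically (1e−12) for N = 1…100.

* **Percus–Yevick hard spheres (3D).** The Wertheim Laplace-space solution
  G(t) = tL(t)/(12η[L(t) + S(t)eᵗ]) is inverted two exact ways: the shell
  (residue) expansion — partial fractions of (−1)ⁿ⁻¹tLⁿ/(12ηSⁿ) at the
  three roots of the cubic S, giving polynomial × exponential closed forms
  per shell — and the pole expansion r g = r + Σ_z Res[G e^{tr}] over the
  complex zeros of L + S eᵗ (the triple zero at t = 0 yields exactly the
  asymptotic 1). The shell sum is exact but its terms grow like e^{t₀x}
  (t₀ > 0 the real root of S) and cancel across shells, so it is used for
  r ≤ 7σ where the cancellation costs at most ~5 digits; the pole sum, with
  enough zeros for 1e−12 at the switch, takes over beyond. Continuity at
  every shell boundary and at the switch is asserted at 1e−8; the contact
  value matches (1 + η/2)/(1 − η)² to 1e−10, and an independent
  Fourier-space inversion of the PY direct correlation function agrees to
  1e−3.

* **FCC crystal.** Coordination shells enumerated exactly from the integer
  lattice {i+j+k even} scaled so the first shell sits at σ; ρ = √2/σ³
  (close packing — `FluidSpec` admits this boundary value). ν and the
  running KBI for the delta-comb RDF are analytic sums over shells.

## Numerical choices

* Grids: uniform, Δr = 1e−3σ; r_max = 50σ (1D), 30σ (3D). Halving Δr moves
  fitted intercepts by <1e−5 (checked).
* **Hard-core step handling.** Tabulated g stores the right limit at
  contact. All quadratures (fluctuation integrals and the convolution)
  treat the step with one-sided limits: the cell below the jump uses the
  left limit, and the convolution half-weights the jump sample. Plain
  trapezoids would instead add a spurious ≈ 4πρ g(σ⁺)Δr/2 to ν(∞) — an
  offset proportional to ρ g(σ⁺) that grows strongly with density.
  Published tabulations of this pipeline that smear the contact over a
  finite cell carry exactly such an offset, and an effective-diameter
  calibration made against them will not zero the modified slope when fed
  exact inputs; with our exact treatment the fitted intercepts converge to
  the closed-form zero-wavevector limit (1 − η)⁴/(1 + 2η)² of the PY
  solution, and the residual modified slope with a = a₃ is ≈ +0.02 rather
  than ≈ 0. The acceptance suite records this discrepancy rather than
  emulating the smearing.
* Asymptote fits: ordinary least squares of ν against 1/L over
  L ∈ [10σ, 0.8·r_max] (≥10 points enforced), with a stability report from
  a 20%-shortened window. The fitted intercepts are insensitive to the
  window at the 1e−3 level for all fluid cases.
* ν̃ curves start at L = a, the smallest physically meaningful subvolume.

## Monte-Carlo oracle

`simulate` provides a canonical Metropolis sampler for 1D hard rods
(N = round(ρL_box), periodic). The state is the gap vector; a single-particle
displacement moves probability between two adjacent gaps and is accepted iff
both stay non-negative — the hard constraint is exact by construction. The
step size is of the order of the mean free gap so dilute systems mix;
sampling every ~10 sweeps after a few thousand equilibration sweeps gives
effectively decorrelated configurations, and runs are bit-reproducible under
a fixed seed.

Windows are placed uniformly at random, so for L_w ≪ L_box they emulate an
open (grand-canonical) subvolume. What the oracle does *not* emulate: the
grand-canonical reservoir exactly — the fixed total N depletes window
fluctuations by a factor between 1 and (1 − L_w/L_box) depending on window
size (at L_w = σ the count is Bernoulli and the ensembles coincide) — and
anything three-dimensional (the 3D oracle role is played by the PY closed
forms; a sphere–sphere overlap volume is provided for future fractional 3D
counting). Tests therefore compare MC estimates to quadrature within
3 batch-means standard errors plus the bounded ensemble term ν·L_w/L_box.
Fractional counting (overlap fraction of each rod with the window) measures
ν̃ directly and independently of the convolution code path; the two routes
agree at the 2.5e−4 level at ρσ = 0.8, L_w = 2σ.

Histogram RDF estimates are normalized with N(N − 1) pair counting (removing
the leading canonical bias) and validated bin-by-bin against the exact Tonks
g at three fillings.

## Problem sizes

Defaults used by the tests and the acceptance script: 3D grids of 30001
points to r_max = 30σ, fluctuation curves of ~460 sizes up to L = 24σ, fits
over L ∈ [10, 24]σ; the MC oracle runs 10⁵ sweeps of 128 rods in a 160σ box
(2×10⁵ window samples). These choices keep every curve grid-converged at the
1e−4 level while the full suite runs in a couple of minutes.

## Known limitations

* The 3D pipeline inherits the Percus–Yevick closure's thermodynamic
  inconsistency: its compressibility-route ν(∞) deviates from
  Carnahan–Starling increasingly with density (−6% at ρ = 0.7), so
  high-density 3D results are structural statements about the PY fluid, not
  about real hard spheres.
* Only uniform (hard) particle profiles: no Gaussian/soft profiles, no
  orientation-averaged nonspherical profiles, no per-species diameters for
  mixtures.
* The modified RDF is meant for *integral* relations (compressibility
  equation and kin). Point statements — the contact theorem, discrete-N
  probabilities P(N) in solvation theory, chemical-potential derivatives —
  need the usual point-particle g and are out of scope.
* 1D and 3D only; no 2D systems; no molecular-dynamics trajectory import.
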