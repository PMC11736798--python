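"""Analytic Percus-Yevick hard-sphere RDF (Wertheim's solution).

The Laplace transform of r*g(r) for the PY hard-sphere fluid is

    G(t) = t L(t) / (12 eta [L(t) + S(t) e^t]),      (sigma = 1)

with L(t) = 12 eta [(1 + eta/2) t + (1 + 2 eta)] and
S(t) = (1-eta)^2 t^3 + 6 eta (1-eta) t^2 + 18 eta^2 t - 12 eta (1+2eta).

Two exact inversions of the same transform are combined:

* Shell (residue) expansion.  Expanding 1/(L + S e^t) in powers of
  L e^{-t}/S gives

      r g(r) = sum_{n>=1} F_n(r - n) theta(r - n),
      F_n = InvLaplace[ (-1)^(n-1) t L^n / (12 eta S^n) ],

  each F_n a closed form: partial fractions at the three roots of S
  (order-n poles) yield polynomial * exp(t_i x) terms.  The expansion is
  exact but the terms grow like exp(t0 x) (t0 > 0 the real root of S) and
  cancel across shells, so it is used only for r <= R_SWITCH where the
  cancellation costs a few digits at most.

* Pole expansion.  Closing the Bromwich contour to the left,

      r g(r) = r + sum_z Res[G(t) e^{t r}, z],

  summed over the complex zeros z of D(t) = L + S e^t with Re z < 0 (the
  triple zero of D at t = 0 produces exactly the leading r, i.e. g -> 1).
  Contributions decay like e^{Re z * r}; enough poles are kept for 1e-12
  accuracy at r = R_SWITCH and the representation only improves beyond.

Continuity of the two routes at R_SWITCH (and of the shell sum at each
integer r) is asserted in the test suite at 1e-8.
"""

from __future__ import annotations

import cmath
import math

import numpy as np

from .errors import TruncationError

R_SWITCH = 7.0
R_MAX_IMPLEMENTED = 200.0
_MAX_POLES = 200


def py_contact(eta: float) -> float:
    """PY contact value g(sigma+) = (1 + eta/2)/(1 - eta)^2."""
    return (1.0 + eta / 2.0) / (1.0 - eta) ** 2


def _poly_LS(eta: float):
    """Coefficients of L (linear) and S (cubic)."""
    l1 = 12.0 * eta * (1.0 + eta / 2.0)
    l0 = 12.0 * eta * (1.0 + 2.0 * eta)
    s = np.array(
        [
            (1.0 - eta) ** 2,
            6.0 * eta * (1.0 - eta),
            18.0 * eta**2,
            -12.0 * eta * (1.0 + 2.0 * eta),
        ]
    )
    return l1, l0, s


def _S_roots(eta: float) -> np.ndarray:
    _, _, s = _poly_LS(eta)
    return np.roots(s)


def _series_mul(a: np.ndarray, b: np.ndarray, order: int) -> np.ndarray:
    return np.convolve(a, b)[:order]


def _series_pow(a: np.ndarray, n: int, order: int) -> np.ndarray:
    out = np.zeros(order, dtype=complex)
    out[0] = 1.0
    for _ in range(n):
        out = _series_mul(out, a, order)
    return out


def _shell_poly_coeffs(eta: float, n: int, roots: np.ndarray) -> list[np.ndarray]:
    """For shell n return, per root t_i, the coefficients c_m of
    F_n^{(i)}(x) = e^{t_i x} sum_m c_m x^m (m = 0..n-1)."""
    l1, l0, _ = _poly_LS(eta)
    one_m_eta2 = (1.0 - eta) ** 2
    sign = (-1.0) ** (n - 1)
    out = []
    fact = np.array([math.factorial(m) for m in range(n)], dtype=float)
    for i in range(3):
        ti = roots[i]
        others = [roots[j] for j in range(3) if j != i]
        # Taylor series in delta = t - t_i, truncated at order n-1
        order = n
        # (t_i + delta)
        t_series = np.zeros(order, dtype=complex)
        t_series[0] = ti
        if order > 1:
            t_series[1] = 1.0
        # L(t_i + delta) = L(t_i) + l1*delta
        L_series = np.zeros(order, dtype=complex)
        L_series[0] = l1 * ti + l0
        if order > 1:
            L_series[1] = l1
        # 1/(d_j + delta) for the two other roots, d_j = t_i - t_j
        inv = np.zeros(order, dtype=complex)
        inv[0] = 1.0
        for tj in others:
            d = ti - tj
            m = np.arange(order)
            inv = _series_mul(inv, (1.0 / d) * (-1.0 / d) ** m, order)
        # phi(delta) = sign/(12 eta) * t * L^n * [inv / (1-eta)^2]^n
        phi = _series_mul(t_series, _series_pow(L_series, n, order), order)
        phi = _series_mul(phi, _series_pow(inv, n, order), order)
        phi *= sign / (12.0 * eta * one_m_eta2**n)
        # A_{ik} = phi[n-k]; coefficient of x^m is A_{i,m+1}/m! = phi[n-1-m]/m!
        out.append(phi[::-1] / fact)
    return out


def _g_shell_region(eta: float, r: np.ndarray) -> np.ndarray:
    """Exact shell expansion of r*g(r)/r for 1 <= r <= R_SWITCH."""
    roots = _S_roots(eta)
    rg = np.zeros_like(r)
    n_max = int(math.floor(r.max() + 1e-12))
    for n in range(1, n_max + 1):
        mask = r >= n
        if not mask.any():
            continue
        x = r[mask] - n
        coeffs = _shell_poly_coeffs(eta, n, roots)
        acc = np.zeros(x.shape, dtype=complex)
        for i in range(3):
            c = coeffs[i]
            # Horner in x
            p = np.full(x.shape, c[-1], dtype=complex)
            for cm in c[-2::-1]:
                p = p * x + cm
            acc += p * np.exp(roots[i] * x)
        rg[mask] += acc.real
    return rg / np.where(r > 0, r, 1.0)


def _denominator_poles(eta: float, r_min: float, tol: float = 1e-13):
    """Zeros z (Im z > 0, Re z < 0) of D(t) = L + S e^t and their residues of
    G(t) = tL/(12 eta D), keeping poles that matter at r >= r_min."""
    l1, l0, s = _poly_LS(eta)

    def L(t):
        return l1 * t + l0

    def S(t):
        return ((s[0] * t + s[1]) * t + s[2]) * t + s[3]

    def Sp(t):
        return (3.0 * s[0] * t + 2.0 * s[1]) * t + s[2]

    def D(t):
        return L(t) + S(t) * cmath.exp(t)

    def Dp(t):
        return l1 + (Sp(t) + S(t)) * cmath.exp(t)

    poles = []
    stale = 0
    for k in range(1, _MAX_POLES + 1):
        # fixed point: t = Log(-L/S) + 2*pi*i*k, then Newton polish
        t = complex(-1.0, 2.0 * math.pi * k)
        for _ in range(200):
            t_new = cmath.log(-L(t) / S(t)) + 2j * math.pi * k
            if abs(t_new - t) < 1e-14:
                t = t_new
                break
            t = t_new
        for _ in range(50):
            step = D(t) / Dp(t)
            t -= step
            if abs(step) < 1e-15 * max(1.0, abs(t)):
                break
        if abs(D(t)) > 1e-8 * max(1.0, abs(S(t) * cmath.exp(t))):
            continue
        res = t * L(t) / (12.0 * eta * Dp(t))
        amp = 2.0 * abs(res) * math.exp(t.real * r_min)
        poles.append((t, res))
        if amp < tol:
            stale += 1
            if stale >= 3:
                break
        else:
            stale = 0
    return poles


def _g_pole_region(eta: float, r: np.ndarray, poles) -> np.ndarray:
    rg = r.astype(float).copy()
    for z, res in poles:
        rg += 2.0 * (res * np.exp(z * r)).real
    return rg / r


def py_rdf_values(eta: float, r) -> np.ndarray:
    """g(r) of the PY hard-sphere fluid at packing fraction eta, r in sigma
    units, on an arbitrary grid of non-negative distances."""
    r = np.asarray(r, dtype=float)
    if r.max() > R_MAX_IMPLEMENTED:
        raise TruncationError(
            f"PY RDF implemented for r <= {R_MAX_IMPLEMENTED} sigma; "
            f"got r_max = {r.max():g}. Reduce r_max."
        )
    g = np.zeros_like(r)
    core = r < 1.0 - 1e-12
    shell = (~core) & (r <= R_SWITCH)
    far = r > R_SWITCH
    if shell.any():
        g[shell] = _g_shell_region(eta, r[shell])
    if far.any():
        poles = _denominator_poles(eta, r_min=R_SWITCH)
        g[far] = _g_pole_region(eta, r[far], poles)
    return g
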