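"""Analytic RDF models: Tonks fluid, Percus-Yevick hard spheres, FCC shells, I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

import nanofluct as nf
from nanofluct._wertheim import R_SWITCH, py_contact, py_rdf_values
from nanofluct.errors import (
    InvalidStateError,
    RDFFormatError,
    UnsupportedModelError,
)


class TestFluidSpec:
    def test_close_packing_rejected_1d(self):
        with pytest.raises(InvalidStateError):
            nf.FluidSpec(rho=1.3, sigma=0.8, dim=1)

    def test_close_packing_rejected_3d(self):
        with pytest.raises(InvalidStateError):
            nf.FluidSpec(rho=1.5, sigma=1.0, dim=3)

    def test_fcc_density_allowed(self):
        # the close-packed crystal sits exactly at eta = pi/sqrt(18)
        spec = nf.FluidSpec(rho=math.sqrt(2.0), sigma=1.0, dim=3)
        assert spec.eta == pytest.approx(nf.ETA_FCC)

    def test_filling_fraction(self):
        assert nf.FluidSpec(rho=0.5, sigma=1.0, dim=3).eta == pytest.approx(math.pi / 12)
        assert nf.FluidSpec(rho=1.0, sigma=0.8, dim=1).eta == pytest.approx(0.8)


class TestTonksNeighborDistribution:
    def test_zero_inside_excluded_range(self, tonks_spec08):
        # the n-th neighbour cannot be closer than n*sigma
        assert nf.tonks_nn_distribution(2, tonks_spec08, 1.5) == 0.0

    def test_normalized(self, tonks_spec08):
        val, _ = quad(lambda r: nf.tonks_nn_distribution(1, tonks_spec08, r), 0.8, 20.0)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_first_neighbor_mean(self, tonks_spec08):
        # <r> = sigma + (1 - rho sigma)/rho = 1.0 at rho=1, sigma=0.8
        val, _ = quad(lambda r: r * nf.tonks_nn_distribution(1, tonks_spec08, r), 0.8, 30.0)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_requires_1d(self):
        spec3 = nf.FluidSpec(rho=0.3, sigma=1.0, dim=3)
        with pytest.raises(UnsupportedModelError):
            nf.tonks_nn_distribution(1, spec3, 1.0)

    @given(n=st.integers(1, 6), t=st.floats(0.05, 0.9))
    def test_normalization_property(self, n, t):
        spec = nf.FluidSpec(rho=t, sigma=1.0, dim=1)
        bp = nf.tonks_pressure(spec)
        hi = n + (n + 60.0) / bp
        val, _ = quad(lambda r: nf.tonks_nn_distribution(n, spec, r), n, hi, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestTonksRDF:
    def test_hard_core(self, tonks_rdf08):
        assert tonks_rdf08(0.5) == 0.0

    def test_contact_value(self, tonks_spec08, tonks_rdf08):
        # g(sigma+) = 1/(1 - rho sigma) = 5; brute-force one-term evaluation
        assert tonks_rdf08(0.8) == pytest.approx(5.0, abs=1e-6)
        brute = nf.tonks_nn_distribution(1, tonks_spec08, 0.8 + 1e-12) / tonks_spec08.rho
        assert tonks_rdf08(0.8) == pytest.approx(brute, abs=1e-6)

    def test_decay_to_unity(self, tonks_rdf08):
        # correlations decay exponentially: still ~2e-4 at 20 sigma,
        # below 1e-6 by 40 sigma
        assert abs(tonks_rdf08(16.0) - 1.0) < 2e-4
        assert abs(tonks_rdf08(32.0) - 1.0) < 1e-6

    @pytest.mark.parametrize("t,L_box", [(0.2, 150.0), (0.5, 120.0), (0.8, 100.0)])
    def test_matches_mc_histogram(self, t, L_box):
        # exact nearest-neighbour-sum RDF vs Monte-Carlo histogram, 3 SE per
        # bin, at three fillings; the oracle is bin-averaged to remove the
        # in-bin curvature bias, and a small floor absorbs the O(1/N)
        # canonical-ensemble correction to g
        spec = nf.FluidSpec(rho=t, sigma=1.0, dim=1)
        configs = nf.sample_tonks(spec, L_box=L_box, n_sweeps=24000, seed=77,
                                  equilibration=3000, sample_every=12)
        bw = 0.1
        est = nf.rdf_histogram(configs, bin_width=bw, r_max=6.0)
        fine = nf.tonks_rdf(spec, nf.default_r_grid(spec, 8.0, 1e-3))
        edges = bw * np.arange(int(6.0 / bw) + 1)
        # average over grid samples in [lo, hi) so the hard-core step is not
        # interpolated across (the grid point at sigma stores the right limit)
        exact_avg = np.array(
            [
                fine.g_values[(fine.r_grid >= lo) & (fine.r_grid < hi - 1e-9)].mean()
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        nb = 20
        batches = np.array_split(configs, nb)
        per_batch = np.array(
            [nf.rdf_histogram(list(b), bin_width=bw, r_max=6.0).g_values for b in batches]
        )
        se = per_batch.std(axis=0, ddof=1) / math.sqrt(nb)
        N = len(configs[0].positions)
        resid = np.abs(est.g_values - exact_avg)
        assert np.all(resid <= 3.0 * se + 2.0 / N), f"rho*sigma={t}"


class TestPercusYevick:
    def test_hard_core(self, py_rdf_cache):
        rdf = py_rdf_cache(0.4)
        assert rdf(0.5) == 0.0

    @pytest.mark.parametrize("rho", [0.2, 0.4, 0.7])
    def test_contact_value(self, rho):
        eta = math.pi * rho / 6.0
        g1 = py_rdf_values(eta, np.array([1.0]))[0]
        assert g1 == pytest.approx(py_contact(eta), rel=1e-10)

    def test_asymptotic_limit(self):
        spec = nf.FluidSpec(rho=0.7, sigma=1.0, dim=3)
        rdf = nf.py_rdf(spec, np.linspace(0.0, 26.0, 26001))
        assert rdf(25.0) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("rho", [0.2, 0.4, 0.7])
    def test_shell_and_switch_continuity(self, rho):
        # piecewise closed forms must join to 1e-8 at every boundary
        eta = math.pi * rho / 6.0
        eps = 1e-9
        bounds = [float(n) for n in range(2, int(R_SWITCH) + 1)] + [R_SWITCH]
        lo = py_rdf_values(eta, np.array(bounds) - eps)
        hi = py_rdf_values(eta, np.array(bounds) + eps)
        assert np.all(np.abs(hi - lo) < 1e-8)

    @pytest.mark.parametrize("rho", [0.1, 0.4, 0.7])
    def test_zero_wavevector_sum_rule(self, py_rdf_cache, rho):
        # 1 + 4 pi rho int (g-1) r^2 dr -> (1-eta)^4/(1+2eta)^2  (eta <= 0.37)
        rdf = py_rdf_cache(rho)
        r, g = rdf.r_grid, rdf.g_values
        f = (g - 1.0) * r**2
        integral = np.trapezoid(f, r)
        # one-sided treatment of the contact step (stored value = right limit)
        j = int(np.searchsorted(r, 1.0))
        integral += 0.5 * (r[j] - r[j - 1]) * r[j] ** 2 * (g[j - 1] - g[j])
        s0 = 1.0 + 4.0 * math.pi * rho * integral
        spec = nf.FluidSpec(rho=rho, sigma=1.0, dim=3)
        closed = nf.py_compressibility_nu(spec).nu_inf
        assert s0 == pytest.approx(closed, rel=1e-2)
        assert s0 == pytest.approx(closed, abs=2e-4)  # quadrature-level agreement

    def test_against_fourier_inversion_oracle(self):
        """Independent route: numerically invert the PY direct correlation
        function through the Ornstein-Zernike relation in Fourier space."""
        rho = 0.3
        eta = math.pi * rho / 6.0
        al = (1 + 2 * eta) ** 2 / (1 - eta) ** 4
        be = -6 * eta * (1 + eta / 2) ** 2 / (1 - eta) ** 4
        ga = eta * (1 + 2 * eta) ** 2 / (2 * (1 - eta) ** 4)
        q = np.arange(5e-4, 3000.0, 5e-4)

        def c_hat(q):
            # 4 pi int_0^1 r^2 (-(al + be r + ga r^3)) sinc(qr) dr, closed form
            s, c = np.sin(q), np.cos(q)
            i2 = (s - q * c) / q**3  # int r^2 sinc
            i3 = (2 * q * s - (q**2 - 2) * c - 2) / q**4  # int r^3 sinc
            i5 = ((4 * q**3 - 24 * q) * s - (q**4 - 12 * q**2 + 24) * c + 24) / q**6
            return -4 * math.pi * (al * i2 + be * i3 + ga * i5)

        ch = c_hat(q)
        hh = ch / (1.0 - rho * ch)
        for r_test in (1.3, 2.0, 3.7, 6.5):
            h = np.trapezoid(q * hh * np.sin(q * r_test), q) / (2 * math.pi**2 * r_test)
            g_direct = py_rdf_values(eta, np.array([r_test]))[0]
            assert g_direct == pytest.approx(1.0 + h, abs=1e-3)

    def test_rejects_wrong_dimension(self, tonks_spec08):
        with pytest.raises(UnsupportedModelError):
            nf.py_rdf(tonks_spec08)


class TestFCCShells:
    def test_first_two_shells(self, fcc):
        assert fcc.shell_distances[0] == pytest.approx(1.0)
        assert fcc.shell_counts[0] == 12
        assert fcc.shell_distances[1] == pytest.approx(math.sqrt(2.0))
        assert fcc.shell_counts[1] == 6

    def test_neighbors_within_two_sigma(self, fcc):
        assert fcc.cumulative_count(2.0) == 12 + 6 + 24 + 12  # shells at 1, v2, v3, 2

    def test_within_two_sigma_excludes_higher(self, fcc):
        assert fcc.cumulative_count(1.5) == 18

    def test_cumulative_matches_supercell_enumeration(self, fcc):
        # brute-force pair count around the origin of a 5x5x5 supercell
        pts = []
        for i in range(-5, 6):
            for j in range(-5, 6):
                for k in range(-5, 6):
                    if (i + j + k) % 2 == 0 and (i, j, k) != (0, 0, 0):
                        pts.append((i, j, k))
        d = np.sqrt(np.sum(np.array(pts, dtype=float) ** 2, axis=1) / 2.0)
        assert fcc.cumulative_count(2.1) == np.count_nonzero(d <= 2.1)

    def test_close_packed_density(self, fcc):
        assert fcc.density == pytest.approx(math.sqrt(2.0))


class TestRDFio:
    def test_round_trip(self, tonks_rdf08, tmp_path):
        p = tmp_path / "g.dat"
        nf.write_rdf(tonks_rdf08, p)
        back = nf.read_rdf(p)
        np.testing.assert_array_equal(back.r_grid, tonks_rdf08.r_grid)
        np.testing.assert_array_equal(back.g_values, tonks_rdf08.g_values)
        assert back.spec == tonks_rdf08.spec

    def test_modified_round_trip(self, tonks_rdf08, tmp_path):
        mod = nf.modify_rdf(tonks_rdf08, 0.8)
        p = tmp_path / "gmod.dat"
        nf.write_rdf(mod, p)
        back = nf.read_rdf(p)
        assert back.includes_diagonal
        assert back.profile_diameter == pytest.approx(0.8)
        np.testing.assert_allclose(back.diagonal_component, mod.diagonal_component)

    def test_non_monotone_grid_rejected(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("# rho = 1.0\n# sigma = 0.8\n# dim = 1\n0.0 0.0\n0.2 0.0\n0.1 1.0\n")
        with pytest.raises(RDFFormatError, match="increasing"):
            nf.read_rdf(p)

    def test_missing_density_metadata_named(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("# sigma = 0.8\n# dim = 1\n0.0 0.0\n0.1 1.0\n")
        with pytest.raises(RDFFormatError, match="rho"):
            nf.read_rdf(p)

    def test_negative_g_rejected(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("# rho = 1.0\n# sigma = 0.8\n# dim = 1\n0.0 0.0\n0.1 -0.5\n")
        with pytest.raises(RDFFormatError, match="negative"):
            nf.read_rdf(p)
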