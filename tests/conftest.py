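import numpy as np
import pytest
from hypothesis import settings

import nanofluct as nf

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tonks_spec08():
    return nf.FluidSpec(rho=1.0, sigma=0.8, dim=1)


@pytest.fixture(scope="session")
def tonks_rdf08(tonks_spec08):
    return nf.tonks_rdf(tonks_spec08)


@pytest.fixture(scope="session")
def py_rdf_cache():
    cache = {}

    def get(rho, r_max=30.0, dr=1e-3):
        key = (rho, r_max, dr)
        if key not in cache:
            spec = nf.FluidSpec(rho=rho, sigma=1.0, dim=3)
            cache[key] = nf.py_rdf(spec, nf.default_r_grid(spec, r_max, dr))
        return cache[key]

    return get


@pytest.fixture(scope="session")
def fcc():
    return nf.fcc_shells(1.0, 12.0)


@pytest.fixture(scope="session")
def mc_configs_half():
    """Canonical hard-rod samples at rho*sigma = 0.5 shared by the oracle tests.

    The box is large (120 sigma) so the O(V_w/V_box) canonical-ensemble
    depletion of open-window fluctuations stays below the statistical noise.
    """
    spec = nf.FluidSpec(rho=0.5, sigma=1.0, dim=1)
    return spec, nf.sample_tonks(spec, L_box=120.0, n_sweeps=20000, seed=1234,
                                 equilibration=2000, sample_every=10)


def ideal_gas_rdf(rho, dim, r_max=20.0, dr=1e-3):
    spec = nf.FluidSpec(rho=rho, sigma=1.0, dim=dim)
    r = nf.default_r_grid(spec, r_max, dr)
    return nf.TabulatedRDF(r, np.ones_like(r), spec)
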