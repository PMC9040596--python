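import numpy as np
import pytest

from soilcosm import GrowthParams, Inoculum, TaxonPool
from soilcosm.synth import make_catalog


@pytest.fixture
def three_taxon_pool() -> TaxonPool:
    return TaxonPool(
        taxon_ids=("a", "b", "c"),
        rel_abundance=np.array([0.9, 0.09, 0.01]),
        growth_rate=np.array([0.4, 0.2, 0.01]),
    )


@pytest.fixture
def single_taxon_pool() -> TaxonPool:
    return TaxonPool(("solo",), np.array([1.0]), np.array([0.4]))


@pytest.fixture
def default_params() -> GrowthParams:
    return GrowthParams()


@pytest.fixture
def small_catalog():
    """Two-strain catalog with distinct copy numbers for correction tests."""
    return make_catalog(n_strains=2, identifier_lengths=(60,), copy_range=(1, 7), seed=11)


def euler_batch(n0, mu, params: GrowthParams, dt: float = 1e-3, s_tol_frac: float = 1e-6):
    """Fixed-step explicit-Euler oracle for the shared-substrate Monod system.

    Deliberately naive: no adaptivity, no event detection. Independent check
    on the production integrator for small taxon counts.
    """
    n = np.asarray(n0, dtype=float).copy()
    s = params.S0
    k = params.c_cell / params.Y
    t = 0.0
    s_tol = s_tol_frac * params.S0
    while s > s_tol and t < 10_000.0:
        growth = mu * (s / (params.K_s + s)) * n * dt
        ds = k * growth.sum()
        if ds > s:  # final partial step: consume exactly the remaining carbon
            growth *= s / ds
            ds = s
        n += growth
        s -= ds
        t += dt
    return n, s, t
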