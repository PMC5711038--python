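import numpy as np
import pytest

import srexchange as sx


@pytest.fixture(scope="session")
def params() -> sx.KineticParameters:
    """Default (cellular) rate constants."""
    return sx.cellular_parameters()


@pytest.fixture(scope="session")
def balanced_params() -> sx.KineticParameters:
    """Rate constants with the cycle closed exactly (Kca = eta * Ksr)."""
    p = sx.cellular_parameters()
    return sx.KineticParameters(
        Ksr=p.Ksr, Ksr_prime=p.Ksr_prime,
        Kca=p.eta * p.Ksr, Kca_prime=p.Kca_prime,
        ksr=p.ksr, ksr_prime=p.ksr_prime, kca=p.kca, kca_prime=p.kca_prime,
    )


@pytest.fixture(scope="session")
def totals_100_560() -> sx.PoolTotals:
    """Cellular pools with the 100/560 receptor split."""
    return sx.cellular_totals()


@pytest.fixture(scope="session")
def totals_30_630() -> sx.PoolTotals:
    """Scarce-cognate-receptor split used in the degradation runs."""
    return sx.PoolTotals(300.0, 100.0, (30.0, 630.0), (300.0,))


@pytest.fixture(scope="session")
def fast_substrate() -> sx.SubstrateParameters:
    """Diffusion-limited substrate (K_D = 10 nM) with lumped degradation."""
    return sx.SubstrateParameters(kon=1e8, koff=1.0, kdeg=0.004, receptor=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
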