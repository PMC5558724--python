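import numpy as np
import pytest

from hybbr import MixturePrior, simulate_dataset
from hybbr.synthetic_data import inference_inputs


@pytest.fixture(scope="session")
def small_scenario():
    """A small simulated reference/validation scenario shared across tests."""
    geno, pheno, truth, vc, E_diag = simulate_dataset(n=400, m=600, seed=11,
                                                      ld_rho=0.3)
    data, aux = inference_inputs(geno, pheno, vc, E_diag, n_validation=80)
    prior = MixturePrior(sigma_g2=truth.mixture_scale)
    return dict(geno=geno, pheno=pheno, truth=truth, vc=vc, E_diag=E_diag,
                data=data, aux=aux, prior=prior)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
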