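import numpy as np
import pytest

from protonrbe import (
    ExperimentSpec,
    LETResponseParams,
    NoiseSpec,
    PhotonReference,
    generate_experiment,
)

#: LET grid of the canonical synthetic family (keV/µm).
FAMILY_LETS = (1.0, 5.0, 10.0, 15.0, 20.0, 25.0)
#: Generating truth for recovery tests.
TRUTH_RESPONSE = LETResponseParams(a_alpha=1.12, b_alpha=0.002, a_beta=0.99, b_beta=0.017)


@pytest.fixture(scope="session")
def photon_ref():
    return PhotonReference("SYN-FIB", alpha_x=2.34, beta_x=0.75)


@pytest.fixture(scope="session")
def truth_response():
    return TRUTH_RESPONSE


def make_family(photon_ref, sigma=0.0, seed=None, let_response=TRUTH_RESPONSE,
                lets=FAMILY_LETS, let_bias=None):
    spec = ExperimentSpec(
        photon_ref=photon_ref,
        let_response=let_response,
        let_values=lets,
        noise=NoiseSpec(sigma=sigma, seed=seed),
        let_bias=let_bias or {},
    )
    return generate_experiment(spec)


@pytest.fixture(scope="session")
def noise_free_family(photon_ref):
    return make_family(photon_ref, sigma=0.0)
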