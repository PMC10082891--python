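import numpy as np
import pytest

from jpet_effcal.geometry import build_scanner
from jpet_effcal.simulate import (
    RegistrationModel,
    SmearingModel,
    SourceConfig,
    simulate_both,
)


@pytest.fixture(scope="session")
def geometry():
    return build_scanner()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_streams(geometry):
    """Common-seed ideal/detector hit tables thinned by the published sigmoid.

    1.2e6 decays yield a few hundred 3-hit groups in a few seconds.
    """
    from jpet_effcal.constants import BSF_REFERENCE
    from jpet_effcal.efficiency import bsf_eval

    source = SourceConfig(n_events=1_200_000, pair_cos_max=0.55)
    smearing = SmearingModel()
    registration = RegistrationModel()
    thinning = lambda e: bsf_eval(BSF_REFERENCE, e)  # noqa: E731
    ideal, det, truth = simulate_both(
        geometry, source, smearing, registration, thinning, seed=42
    )
    return ideal, det, truth


@pytest.fixture(scope="session")
def unsmeared_hits(geometry):
    """Hit table with every smearing disabled (exact times/positions/energies)."""
    source = SourceConfig(n_events=800_000, pair_cos_max=0.55)
    smearing = SmearingModel(sigma_t_ns=0.0, sigma_z_cm=0.0, energy_res_coeff=0.0)
    registration = RegistrationModel()
    ideal, _, truth = simulate_both(
        geometry, source, smearing, registration, None, seed=77
    )
    return ideal, truth
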