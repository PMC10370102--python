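import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from fluorofit import PeptideDesign, SequencingParams, build_state_space

# property tests must behave identically on every run
hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_design() -> PeptideDesign:
    """One channel, labels at positions 1 and 2, three Edman cycles."""
    return PeptideDesign(labels_by_channel=((1, 2),), n_cycles=3)


@pytest.fixture(scope="session")
def tiny_params() -> SequencingParams:
    return SequencingParams(
        edman_failure_rate=0.10,
        detach_rate=0.02,
        initial_block_rate=0.07,
        cyclic_block_rate=0.03,
        dye_loss_rate=(0.05,),
        dud_rate=(0.10,),
        mu=(6000.0,),
        sigma=(700.0,),
        bg_mu=0.0,
        bg_sigma=350.0,
    )


@pytest.fixture(scope="session")
def tiny_space(tiny_design):
    return build_state_space(tiny_design)


@pytest.fixture(scope="session")
def one_label_design() -> PeptideDesign:
    return PeptideDesign(labels_by_channel=((2,),), n_cycles=4)


def random_params(rng: np.random.Generator, n_channels: int = 1) -> SequencingParams:
    """Valid random parameter vector for property tests."""
    r = lambda: float(rng.uniform(0.0, 0.4))  # noqa: E731
    return SequencingParams(
        edman_failure_rate=r(),
        detach_rate=r(),
        initial_block_rate=r(),
        cyclic_block_rate=r(),
        dye_loss_rate=tuple(r() for _ in range(n_channels)),
        dud_rate=tuple(r() for _ in range(n_channels)),
        mu=tuple(float(rng.uniform(3000, 9000)) for _ in range(n_channels)),
        sigma=tuple(float(rng.uniform(300, 1200)) for _ in range(n_channels)),
        bg_mu=0.0,
        bg_sigma=float(rng.uniform(100, 600)),
    )
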