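import numpy as np
import pytest

from fnirsfc.montage import build_standard_montage, load_default_montage
from fnirsfc.preprocess import RoiTimeSeries
from fnirsfc.synthetic import SimulationConfig, generate_roi_latents

REFERENCE_EXCLUDED_CHANNELS = {1, 10, 12, 20, 22, 31}


@pytest.fixture(scope="session")
def montage():
    return load_default_montage()


@pytest.fixture(scope="session")
def retained_montage(montage):
    return montage.restrict(
        [c for c in montage.channel_ids if c not in REFERENCE_EXCLUDED_CHANNELS]
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_per_group=6, seed=42)


@pytest.fixture(scope="session")
def latent_cohort(small_config):
    """Noise-free latent ROI series for 12 participants (6 per group)."""
    out = []
    for i in range(small_config.n_total):
        traces, _ = generate_roi_latents(small_config, i)
        out.append(
            RoiTimeSeries(
                traces=traces,
                roi_order=small_config.roi_names,
                sampling_rate=small_config.sampling_rate,
                participant_id=small_config.participant_id(i),
                group=small_config.group_of(i),
            )
        )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
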