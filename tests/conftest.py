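import numpy as np
import pytest

from shadematch.pipeline import calibrate_device
from shadematch.shade_db import build_database
from shadematch.synthetic_data import (
    DeviceProfile,
    default_palette,
    make_device_profiles,
    simulate_device_dataset,
)


@pytest.fixture(scope="session")
def palette():
    return default_palette(0)


@pytest.fixture(scope="session")
def identity_db(palette):
    """Reference database from 5 perfect devices x 7 repeats (no noise)."""
    rng = np.random.default_rng(0)
    records = []
    for dev in range(1, 6):
        records += simulate_device_dataset(
            palette, DeviceProfile.identity(dev), 7, rng
        )
    return build_database(records)


@pytest.fixture(scope="session")
def noisy_family(palette):
    """8 default-imperfection devices with per-device CCMs and datasets."""
    profiles = make_device_profiles(8, seed=11)
    rng = np.random.default_rng(11)
    ccms = {p.device_id: calibrate_device(palette, p, rng)[0] for p in profiles}
    datasets = {
        p.device_id: simulate_device_dataset(
            palette, p, 7, rng, ccm=ccms[p.device_id]
        )
        for p in profiles
    }
    return {"profiles": profiles, "ccms": ccms, "datasets": datasets}
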