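import numpy as np
import pytest

from mseeg.preproc import REGION_BASES, Recording, RegionScheme


def toy_scheme(channel_labels, excluded=()):
    """22-region scheme over an arbitrary channel list (round-robin)."""
    regions = [f"{b}_{h}" for b in REGION_BASES for h in ("L", "R")]
    labs = [c for c in channel_labels if c not in excluded]
    assert len(labs) >= 22, "need >= 22 channels for a full toy scheme"
    mapping = {c: regions[i % 22] for i, c in enumerate(labs)}
    return RegionScheme(region_labels=regions, channel_to_region=mapping,
                        excluded_channels=set(excluded))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """10 s of 8-channel white noise at 250 Hz, average-referenced."""
    data = rng.normal(0, 20, (8, 2500))
    data -= data.mean(axis=0, keepdims=True)
    return Recording(data=data, sampling_rate=250.0, reference="average")
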