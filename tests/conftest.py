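import numpy as np
import pandas as pd
import pytest

from tripletmmn import paradigm, synth_eeg


@pytest.fixture(scope="session")
def tt() -> paradigm.TransitionTable:
    return paradigm.TransitionTable()


@pytest.fixture(scope="session")
def stream_cfg() -> paradigm.StreamConfig:
    return paradigm.StreamConfig()


@pytest.fixture(scope="session")
def montage() -> synth_eeg.MontageSpec:
    return synth_eeg.default_montage()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_events() -> pd.DataFrame:
    """Hand-built three-triplet event table on a 300 ms grid."""
    rows = []
    t = 0.0
    cats = ["standard", "stat_deviant", "phys_deviant"]
    for k, cat in enumerate(cats):
        for pos, sound in (("root1", "A"), ("root2", "B")):
            rows.append(
                dict(onset_ms=t, block=1, triplet_index=k, position=pos,
                     sound=sound, side="left", category="root", is_target=False)
            )
            t += 300.0
        rows.append(
            dict(onset_ms=t, block=1, triplet_index=k, position="ending",
                 sound="E", side="left", category=cat, is_target=False)
        )
        t += 300.0
    return pd.DataFrame(rows)
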