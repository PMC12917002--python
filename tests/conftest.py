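import numpy as np
import pandas as pd
import pytest

from somnostat.signal_io import Hypnogram
from somnostat.simulate import (
    EventPlan,
    NoiseSpec,
    StagePlan,
    generate_hypnogram,
    synthesize_recording,
)


@pytest.fixture(scope="session")
def n2_hypnogram_30min() -> Hypnogram:
    """60 epochs of pure N2."""
    return Hypnogram(np.array(["N2"] * 60))


@pytest.fixture(scope="session")
def planted_sw_recording(n2_hypnogram_30min):
    """30-min N2 recording, Cz, 150 planted canonical slow waves in pink noise."""
    rng = np.random.default_rng(12345)
    onsets = np.sort(rng.uniform(2.0, 30 * 60 - 4.0, 200))
    onsets = onsets[np.concatenate(([True], np.diff(onsets) > 2.2))]
    events = [EventPlan("slow_wave", "Cz", float(t), 1.0, 80.0) for t in onsets]
    rec, truth = synthesize_recording(
        n2_hypnogram_30min, events=events, noise=NoiseSpec("pink", 10.0, 777)
    )
    return rec, truth


@pytest.fixture()
def event_table() -> pd.DataFrame:
    """A small well-formed event table."""
    n = 20
    rng = np.random.default_rng(5)
    start = np.sort(rng.uniform(0, 500, n))
    dur = rng.uniform(0.8, 1.2, n)
    return pd.DataFrame(
        {
            "kind": "slow_wave",
            "channel": "Cz",
            "start_s": start,
            "end_s": start + dur,
            "trough_amplitude_uv": -rng.uniform(35, 60, n),
            "p2p_amplitude_uv": rng.uniform(60, 110, n),
            "duration_s": dur,
            "frequency_hz": 1.0 / dur,
            "stage": "N2",
            "qc_flag": False,
        }
    )
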