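import numpy as np
import pytest

from seegdecode import (
    EpochSet,
    Recording,
    SynthConfig,
    TFRConfig,
    build_schedule,
    simulate_recording,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-contact effect-free cohort with a shortened schedule, shared by
    tests that only exercise plumbing (not the study conditions)."""
    cfg = SynthConfig(
        n_contacts=2,
        presentations_per_modality=8,
        region_labels={"A": "superiortemporal", "B": "putamen"},
        seed=11,
    )
    schedule = build_schedule(cfg, seed=11)
    rec, manifest = simulate_recording(schedule, cfg, seed=11)
    return cfg, schedule, rec, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def sinusoid_epochs(freq_hz=10.0, n_epochs=3, sfreq=1000.0, amp=1.0):
    """Pure-sinusoid epoch set on one channel, (-1, 1) s window."""
    t = -1.0 + np.arange(int(2 * sfreq)) / sfreq
    data = amp * np.sin(2 * np.pi * freq_hz * t)[None, None, :].repeat(n_epochs, axis=0)
    return EpochSet(
        data=data,
        window=(-1.0, 1.0),
        condition=np.array(["stimulus"] * n_epochs, dtype=object),
        modality=np.array([""] * n_epochs, dtype=object),
        sfreq=sfreq,
        ch_names=["ch0"],
    )


@pytest.fixture()
def fast_tfr():
    """Coarse TFR configuration for unit tests."""
    return TFRConfig(freqs_hz=np.geomspace(4, 120, 16), decim=12)
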