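import numpy as np
import pytest

from betaclc import spectral, synth

F0 = 28.0
FS = 1000.0


@pytest.fixture(scope="session")
def meso300():
    """300-s stationary meso pair (no trials / no desynchronization)."""
    return synth.generate_meso_lfp(None, 300.0, desync=None, seed=11)


@pytest.fixture(scope="session")
def beta300(meso300):
    """Normalized 28-Hz analytic signal of the left meso signal."""
    return spectral.normalize_amplitude(
        spectral.filter_signal(meso300.s_L, F0, fs=FS)
    )


@pytest.fixture(scope="session")
def beta300_right(meso300):
    return spectral.normalize_amplitude(
        spectral.filter_signal(meso300.s_R, F0, fs=FS)
    )


@pytest.fixture(scope="session")
def task_dataset():
    """120-s task recording (trials, desynchronization) for both tasks."""
    out = {}
    for ti, task in enumerate(("BC", "MC")):
        trials = synth.generate_trials(task, 26, seed=5 + ti)
        assert trials["t_reward_off"].max() < 119_000
        meso = synth.generate_meso_lfp(trials, 120.0, seed=20 + ti)
        sig = spectral.normalize_amplitude(
            spectral.filter_signal(meso.s_L, F0, fs=FS)
        )
        out[task] = {"trials": trials, "meso": meso, "sig": sig}
    return out
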