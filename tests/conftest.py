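import numpy as np
import pandas as pd
import pytest

from romkit import (
    KinematicScenario,
    NoiseModel,
    builtin_registry,
    lookup,
    simulate_trial,
)


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def back_flexion():
    return lookup("Back Flexion and Extension")


@pytest.fixture()
def clean_trial(back_flexion):
    """Noiseless 60-degree back-flexion trial, webcam dialect."""
    scenario = KinematicScenario(movement=back_flexion, true_rom=60.0)
    return simulate_trial(scenario, NoiseModel(seed=0))


@pytest.fixture()
def noisy_trial(back_flexion):
    scenario = KinematicScenario(movement=back_flexion, true_rom=60.0)
    noise = NoiseModel(landmark_sigma=0.005, seed=7)
    return simulate_trial(scenario, noise)


def make_trial(spec, dialect="pose33", true_rom=60.0, noise=None, **kwargs):
    scenario = KinematicScenario(movement=spec, true_rom=true_rom, **kwargs)
    return simulate_trial(scenario, noise or NoiseModel(seed=0), dialect=dialect)


@pytest.fixture(scope="session")
def rom_table_factory():
    """Long ROM tables with a known variance structure, no trajectory step."""

    def build(n_subjects=10, n_trials=3, mean=60.0, bsd=10.0, wsd=3.0,
              devices=("pose33", "mocap39"), seed=0, movement="Test Movement"):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subjects):
            subj_rom = rng.normal(mean, bsd)
            for trial in range(1, n_trials + 1):
                latent = rng.normal(subj_rom, wsd)
                for device in devices:
                    rows.append(
                        {"subject": f"S{i:02d}", "movement": movement,
                         "device": device, "trial": trial, "rom": latent,
                         "usable": True}
                    )
        return pd.DataFrame(rows)

    return build
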