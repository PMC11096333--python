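import numpy as np
import pytest

from ospipe import design, montage, simulate


@pytest.fixture(scope="session")
def default_schedule():
    """Full-size schedule: both conditions, 20 presentations, 50% omission."""
    return design.build_schedule(design.default_specs_both_conditions(),
                                 20, 0.5, seed=11)


@pytest.fixture(scope="session")
def small_schedule():
    """Cheap schedule (both conditions, 25 omissions per condition)."""
    return design.build_schedule(design.default_specs_both_conditions(),
                                 2, 0.5, seed=7)


@pytest.fixture()
def toy_epochs():
    """Deterministic 3-epoch set for container-level tests."""
    rng = np.random.default_rng(5)
    n_ch = len(montage.CHANNELS)
    t = np.arange(-200.0, 301.0)
    data = rng.normal(0.0, 1.0, size=(3, n_ch, len(t)))
    return simulate.EpochSet(
        data=data, time_axis=t, labels=np.array(["E", "F", "A"]),
        retained=np.ones(3, dtype=bool), fs=1000.0, condition="familiar",
        participant_id="sub-01",
    )


def quiet_config(**overrides):
    """Noise-free simulation config used across tests."""
    base = dict(
        n_participants=1, noise_sd=0.0, oN1_within_sd=0.0,
        artifact_fraction=0.0,
        note_pattern_amp={"familiar": 0.0, "unfamiliar": 0.0},
        oN1_between_sd={"familiar": 0.0, "unfamiliar": 0.0},
    )
    base.update(overrides)
    return simulate.SimulationConfig(**base)
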