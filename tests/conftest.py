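import numpy as np
import pandas as pd
import pytest

import whatwhere as ww


@pytest.fixture
def screen() -> ww.ScreenSpec:
    return ww.ScreenSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1)


@pytest.fixture
def schedule() -> list[ww.TrialSpec]:
    """A standard 120-trial session schedule."""
    return ww.generate_schedule(seed=1)


@pytest.fixture
def simulated_session(schedule, rng):
    """(trial, response) pairs under a mid-range mixture."""
    params = ww.MixtureParams(0.6, 0.2, 0.2, sigma_px=30.0, p_identify=0.9)
    responses = ww.simulate_session(schedule, params, rng)
    return list(zip(schedule, responses))


@pytest.fixture
def tiny_cohort() -> list[ww.ParticipantRecord]:
    """Two small groups with short sessions, volumes and ACE."""
    spec = ww.clinical_cohort_spec(n_per_group=3, seed=11, n_per_condition=3)
    return ww.simulate_cohort(spec)


def rm_fixture() -> pd.DataFrame:
    """6-subject 2x2 within-subject table; oracle F values frozen in tests."""
    rng = np.random.default_rng(42)
    rows = []
    for s in range(6):
        base = rng.normal(10, 2)
        for i, ss in enumerate((1, 3)):
            for j, d in enumerate((1.0, 4.0)):
                y = base + 1.5 * i + 0.8 * j + 0.5 * i * j + rng.normal(0, 1)
                rows.append(
                    dict(participant_id=f"p{s}", set_size=ss, delay_s=d, y=y)
                )
    return pd.DataFrame(rows)


def mixed_fixture() -> pd.DataFrame:
    """3 groups x 4 subjects x 2x2 within; oracle F values frozen in tests."""
    rng = np.random.default_rng(43)
    rows = []
    for gi, g in enumerate(("a", "b", "c")):
        for s in range(4):
            base = rng.normal(10 + gi, 2)
            for i, ss in enumerate((1, 3)):
                for j, d in enumerate((1.0, 4.0)):
                    y = (base + 1.2 * i + 0.6 * j + 0.3 * i * j
                         + 0.4 * gi * i + rng.normal(0, 1))
                    rows.append(
                        dict(participant_id=f"{g}{s}", group=g,
                             set_size=ss, delay_s=d, y=y)
                    )
    return pd.DataFrame(rows)
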