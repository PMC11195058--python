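import numpy as np
import pandas as pd
import pytest

from organclock import SimulationConfig, generate_cohort, simulate_cohort


@pytest.fixture(scope="session")
def cohort800():
    """Mid-size cohort with proteome, events and MCAR missingness."""
    return simulate_cohort(SimulationConfig(n_subjects=800, seed=11))


@pytest.fixture(scope="session")
def cohort800_clean():
    """Same size, no missingness — for clock/FIBA tests."""
    return simulate_cohort(
        SimulationConfig(n_subjects=800, seed=12, missing_rate=0.0)
    )


@pytest.fixture(scope="session")
def gaps20k():
    """Large gaps-only cohort (no proteome) for distributional checks."""
    cfg = SimulationConfig(n_subjects=20_000, seed=13)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def brain_clock(cohort800_clean):
    from organclock import fit_clock

    b = cohort800_clean
    panel = b.ground_truth["panels"]["brain"]
    return fit_clock(
        b.proteomes[0], b.ages(0), panel=panel, name="brain", random_state=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
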