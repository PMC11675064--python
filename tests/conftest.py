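import numpy as np
import pytest

import reachbias as rb


@pytest.fixture(scope="session")
def layout():
    return rb.build_default_layout()


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort with a fixed, mid-range cursor-bias weight.

    Shared by the simulation/preprocessing/report tests that only need
    realistic records, so the cohort is simulated once per session.
    """
    pop = rb.PopulationParams(cursor_bias_w=(0.5, 0.5))
    return rb.simulate_experiment(
        6, population=pop, seed=11, simulate_fillers=False
    )


@pytest.fixture(scope="session")
def small_binned(small_cohort):
    return rb.preprocess_records(small_cohort)
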