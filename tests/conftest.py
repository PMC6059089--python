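import numpy as np
import pytest

from ectogas.core import cohort_to_frame
from ectogas.correction import correct_frame
from ectogas.simulate import SimulationConfig, default_config, generate_cohort, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default study-sized cohort with artifacts, fixed seed."""
    return simulate_cohort(default_config(seed=20260929))


@pytest.fixture(scope="session")
def clean_cohort():
    """Artifact-free default cohort (no missingness, no outliers)."""
    cfg = default_config(seed=20260930)
    cfg = SimulationConfig(**{**cfg.__dict__, "missing_rates": {}, "outlier_rate": 0.0})
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def corrected_frame(default_cohort):
    """Default cohort flattened and temperature-corrected."""
    frame = cohort_to_frame(default_cohort.observations)
    return correct_frame(frame.dropna(subset=["ta_c"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
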