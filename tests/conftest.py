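import numpy as np
import pytest

from omisurv.containers import OmicsMatrix, SurvivalData
from omisurv.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort with strong signal, reused across tests."""
    return generate_cohort(
        SimConfig(
            n_samples=120,
            n_features=(60, 60, 40),
            effect_size=2.0,
            hazard_ratio=4.0,
            censor_scale=300.0,
            seed=42,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_survival(rng, n, censor_frac=0.3):
    """Mixed-censoring survival data for metric tests."""
    time = rng.exponential(50.0, size=n) + 1e-3
    event = (rng.random(n) > censor_frac).astype(int)
    return SurvivalData(time, event, [f"S{i}" for i in range(n)])


def toy_block(values, kind="expression", prefix="f"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsMatrix(
        values,
        [f"S{i}" for i in range(n)],
        [f"{prefix}{j}" for j in range(p)],
        kind,
    )
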