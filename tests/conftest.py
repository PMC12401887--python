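import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermoreg import PairedSeries, RunConfig, Treatment, run_pipeline

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_series(
    t_leaf,
    t_air,
    minutes=None,
    plant_id="P1",
    treatment=Treatment.BENIGN,
    start_minute=750.0,
):
    """Build a PairedSeries from raw arrays with 1-min spacing by default."""
    t_leaf = np.asarray(t_leaf, dtype=float)
    if minutes is None:
        minutes = start_minute + np.arange(t_leaf.size, dtype=float)
    return PairedSeries(
        plant_id=plant_id,
        treatment=treatment,
        minutes=np.asarray(minutes, dtype=float),
        t_leaf=t_leaf,
        t_air=np.asarray(t_air, dtype=float),
    )


@pytest.fixture(scope="session")
def default_run():
    """One full simulated-experiment pipeline run, shared across tests."""
    return run_pipeline(RunConfig(simulate=True, seed=11, n_boot=200))
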