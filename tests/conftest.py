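import numpy as np
import pytest

from anomort.model import ModelSpec
from anomort.synth import make_dataset, make_lattice_states, simulate_anomalies


@pytest.fixture(scope="session")
def small_dataset():
    """6 lattice states, 5 years, one stratum — fast enough for unit tests."""
    return make_dataset(2, 3, 5, seed=1)


@pytest.fixture(scope="session")
def glm_instance():
    """3 states, 24 months, no random effects, common anomaly coefficient.

    A plain Poisson GLM in (time, anomaly), small enough for grid oracles.
    """
    from anomort.model import LatentState, linear_predictor_matrix

    G, states = make_lattice_states(1, 3)
    components = {
        "spatial": False, "seasonal": False, "interaction": False,
        "time_rw": False, "anomaly": True, "overdispersion": False,
    }
    spec = ModelSpec(adjacency=G, n_times=24, state_labels=states,
                     components=components, gamma_mode="common")
    rng = np.random.default_rng(5)
    anoms = simulate_anomalies(states, [2000, 2001], seed=rng)
    A = (
        anoms.assign(_t=(anoms["year"] - 2000) * 12 + anoms["month"] - 1)
        .pivot_table(index="unit_id", columns="_t", values="anomaly")
        .reindex(index=states)
        .to_numpy()
    )
    truth = LatentState.zeros(spec)
    truth.alpha0, truth.beta0, truth.gamma = -8.0, 0.003, 0.03
    P = np.full((3, 24), 5.0e5)
    mu = np.exp(linear_predictor_matrix(truth, spec, A)) * P
    y = rng.poisson(mu)
    return dict(spec=spec, anomaly=A, population=P, deaths=y, truth=truth)
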