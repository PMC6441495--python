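import numpy as np
import pytest

import mtorstress as m
from mtorstress.data import NoiseModel
from mtorstress.simulate import DEFAULT_TIMES, standard_conditions


@pytest.fixture(scope="session")
def model_V():
    return m.build_model("V")


@pytest.fixture(scope="session")
def model_III():
    return m.build_model("III")


@pytest.fixture(scope="session")
def truth_V():
    return m.ground_truth_params("V")


@pytest.fixture(scope="session")
def truth_III():
    return m.ground_truth_params("III")


@pytest.fixture(scope="session")
def all_conditions():
    """The three perturbation regimes plus their no-stress companions."""
    conds = dict(standard_conditions())
    for lab in list(conds):
        comp = conds[lab].no_stress_companion()
        conds[comp.label] = comp
    return conds


@pytest.fixture(scope="session")
def noisefree_study_V(model_V, truth_V, all_conditions):
    """Noise-free single-replicate datasets for the three stressed regimes."""
    labels = ("arsenite", "arsenite_wortmannin", "arsenite_mk2206")
    return [
        m.generate_dataset(
            model_V, truth_V, all_conditions[lab], DEFAULT_TIMES, 1, NoiseModel(cv=0.0, seed=0)
        )
        for lab in labels
    ]


@pytest.fixture(scope="session")
def noisy_study_III(model_III, truth_III, all_conditions):
    """Noisy synthetic study from the two-input truth, with companions."""
    labels = ("arsenite", "arsenite_wortmannin", "arsenite_mk2206")
    return m.generate_study(
        model_III,
        truth_III,
        [all_conditions[lab] for lab in labels],
        DEFAULT_TIMES,
        n_reps=4,
        noise=NoiseModel(cv=0.15, seed=7),
    )


@pytest.fixture(scope="session")
def random_states():
    """Admissible random states: non-negative, strictly inside pool totals."""
    rng = np.random.default_rng(42)
    states = []
    for _ in range(20):
        x = rng.uniform(0.01, 1.0, size=25)
        states.append(x)
    return states
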