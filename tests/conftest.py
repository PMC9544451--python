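import numpy as np
import pytest

from cureph.data import CensoringType, Dataset
from cureph.likelihood import LikelihoodWorkspace
from cureph.simulate import generate_dataset, study1_scenario, study2_scenario
from cureph.splines import SplineBasis, place_knots


@pytest.fixture(scope="session")
def mixed_dataset():
    """Small partly interval-censored dataset (all four censoring types)."""
    scn = study1_scenario(n=120, tau=3.0, delta_exact=0.45, seed=7)
    return generate_dataset(scn)


@pytest.fixture(scope="session")
def event_right_dataset():
    """Right-censoring-only dataset (events + right censoring)."""
    scn = study2_scenario(n=150, tau=2.9, seed=11)
    return generate_dataset(scn)


@pytest.fixture(scope="session")
def mixed_workspace(mixed_dataset):
    basis = place_knots(mixed_dataset, n_internal=3)
    return LikelihoodWorkspace(mixed_dataset, basis)


@pytest.fixture(scope="session")
def cubic_basis():
    return SplineBasis(order=4, interior_knots=np.array([0.4, 0.9, 1.4]),
                       boundary=(0.1, 2.0))


def make_dataset(t_left, t_right, status, X=None, Z=None):
    n = len(t_left)
    if X is None:
        X = np.zeros((n, 1))
    if Z is None:
        Z = np.column_stack([np.ones(n), np.zeros(n)])
    return Dataset(t_left, t_right, status, X, Z)
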