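import numpy as np
import pytest

from survflow import SurvivalDataset
from survflow.simulate import SimulationConfig, simulate_ph_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(times, events, covariates=None, feature_names=None, groups=None):
    times = np.asarray(times, dtype=float)
    n = len(times)
    if covariates is None:
        covariates = np.zeros((n, 0))
        feature_names = ()
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates.reshape(-1, 1)
    if feature_names is None:
        feature_names = tuple(f"x{j + 1}" for j in range(covariates.shape[1]))
    return SurvivalDataset(
        subject_ids=np.array([f"S{i}" for i in range(n)], dtype=object),
        time=times,
        event=np.asarray(events, dtype=int),
        covariates=covariates,
        feature_names=feature_names,
        groups=None if groups is None else np.asarray(groups, dtype=object),
    )


def random_censored(rng, n, cens_frac=0.3):
    """Continuous (tie-free) random right-censored data."""
    t = rng.exponential(10.0, n)
    e = (rng.uniform(size=n) > cens_frac).astype(int)
    if e.sum() == 0:
        e[0] = 1
    return t, e


@pytest.fixture
def small_sim():
    ds, truth = simulate_ph_dataset(SimulationConfig(n=200, beta=(0.8, 0.0), seed=42))
    return ds, truth
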