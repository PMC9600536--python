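import numpy as np
import pytest

from temporules.data import MicrobiomeDataset
from temporules.embedding import build_embedding
from temporules.inference import FitConfig, initialize
from temporules.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small simulated cohort shared by model/inference tests."""
    config = SimulationConfig(n_subjects=8, n_timepoints=8, n_taxa=10, seed=11)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def tiny_embedding(tiny_cohort):
    ds, _ = tiny_cohort
    return build_embedding(ds.distances)


@pytest.fixture(scope="session")
def tiny_setup(tiny_cohort, tiny_embedding):
    """(dataset, embedding, params, priors) for a 2x2 model on the tiny cohort."""
    ds, _ = tiny_cohort
    config = FitConfig(n_rules=2, n_detectors=2, seed=5)
    params, priors = initialize(ds, tiny_embedding, config)
    return ds, tiny_embedding, params, priors


def make_manual_dataset(abundances, times, labels, distances=None, taxa=None,
                        mask=None):
    """Assemble a MicrobiomeDataset from raw arrays for hand-built cases."""
    abundances = np.asarray(abundances, dtype=float)
    S, T, N = abundances.shape
    taxa = taxa or [f"T{i}" for i in range(N)]
    if distances is None:
        distances = np.abs(np.subtract.outer(np.arange(N), np.arange(N))).astype(float)
    ds = MicrobiomeDataset(
        subjects=[f"S{i}" for i in range(S)],
        labels=np.asarray(labels, dtype=int),
        taxa=taxa,
        times=np.asarray(times, dtype=float),
        abundances=abundances,
        mask=np.ones((S, T), dtype=bool) if mask is None else np.asarray(mask),
        distances=np.asarray(distances, dtype=float),
    )
    ds.validate()
    return ds
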