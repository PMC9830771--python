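import numpy as np
import pandas as pd
import pytest

from scnet.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """40-region cross-sectional cohort, 30 subjects/group."""
    return generate_cohort(
        SyntheticSpec(n_regions=40, n_subjects_per_group=30, seed=42)
    )


@pytest.fixture(scope="session")
def longitudinal_cohort() -> pd.DataFrame:
    """40-region paired cohort: baseline and follow-up per subject."""
    return generate_cohort(
        SyntheticSpec(n_regions=40, n_subjects_per_group=20, longitudinal=True, seed=7)
    )


def random_connected_adjacency(rng: np.random.Generator, n: int, p: float = 0.35):
    """Rejection-sample a connected Erdos-Renyi adjacency matrix."""
    from scnet.networks import is_connected

    while True:
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, k=1)
        adj = adj | adj.T
        if is_connected(adj):
            return adj
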