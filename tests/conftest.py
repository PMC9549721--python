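import numpy as np
import pandas as pd
import pytest

from vertmorph import (CornerLandmarks, compute_dataset_metrics, default_cohort_spec,
                       generate_cohort)
from vertmorph.metrics import METRIC_COLUMNS

SEED = 0


@pytest.fixture
def square_lm():
    """Unit square: PI(0,0), PS(0,1), AI(1,0), AS(1,1)."""
    return CornerLandmarks((1, 1), (0, 1), (1, 0), (0, 0))


@pytest.fixture
def anterior_wedge_lm():
    """Anterior height 0.8, superior endplate tilted down anteriorly."""
    return CornerLandmarks((1, 0.8), (0, 1), (1, 0), (0, 0))


@pytest.fixture
def posterior_wedge_lm():
    """Posterior height 0.8, superior endplate tilted up anteriorly."""
    return CornerLandmarks((1, 1), (0, 0.8), (1, 0), (0, 0))


@pytest.fixture(scope="session")
def lumbar_cohort():
    """A seeded 500-subject lumbar cohort with 5% contamination plus its truth."""
    spec = default_cohort_spec(region="lumbar", n_subjects=500,
                               contamination_rate=0.05, seed=SEED)
    dataset, truth = generate_cohort(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def lumbar_metrics(lumbar_cohort):
    """Metrics table of the session cohort."""
    _, dataset, _ = lumbar_cohort
    table, rejects = compute_dataset_metrics(dataset)
    assert len(rejects) == 0
    return table


@pytest.fixture
def gaussian_metrics():
    """Factory for i.i.d. Gaussian metrics tables (one stratum)."""

    def make(n, seed=SEED, region="lumbar", level="L1", mean=0.0, sd=1.0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)],
                           "region": region, "level": level})
        for m in METRIC_COLUMNS:
            df[m] = rng.normal(mean, sd, n)
        return df

    return make
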