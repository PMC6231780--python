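import numpy as np
import pytest

import phenogroup as pg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_group_cohort():
    """Well-separated 2-group cohort (8/group, 20 weeks, sigma=1)."""
    cfg = pg.two_group_orthogonal_config(seed=3)
    cohort, labels = pg.generate_grouped_cohort(cfg)
    return cohort, labels


@pytest.fixture(scope="session")
def two_group_datasets(two_group_cohort):
    cohort, labels = two_group_cohort
    datasets = pg.cohort_to_datasets(cohort)
    truth = labels.set_index("participant_id")["true_group"]
    return datasets, truth


@pytest.fixture(scope="session")
def standardized_two_group(two_group_datasets):
    """Datasets with cohort-wide z-scored features, as the DP sampler sees them."""
    datasets, truth = two_group_datasets
    X = np.vstack([d.X for d in datasets])
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    zdata = [
        pg.IndividualDataset(d.participant_id, (d.X - mean) / sd, d.y, d.cohort_label)
        for d in datasets
    ]
    return zdata, truth
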