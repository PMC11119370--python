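import numpy as np
import pytest

from connectrl import (
    CohortConfig,
    compare_groups,
    fc_for_cohort,
    generate_cohort,
)
from connectrl.pipeline import profiles_for_cohort


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down two-group study: 20 regions, strong localized effect."""
    return CohortConfig(
        n_group_a=20,
        n_group_b=24,
        n_regions=20,
        n_timepoints=240,
        n_modules=4,
        effect_regions=(2, 5, 11),
        effect_multiplier=0.7,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    return profiles_for_cohort(fc_for_cohort(small_cohort))


@pytest.fixture(scope="session")
def small_table(small_profiles):
    return compare_groups(small_profiles)


def random_stable_symmetric(n: int, rng: np.random.Generator):
    """Random symmetric matrix normalized to spectral norm < 1."""
    m = rng.uniform(-1.0, 1.0, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m / (1.0 + np.linalg.norm(m, 2))


def pair_count_auc(scores, labels):
    """AUC as the Mann-Whitney concordance probability (brute force)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)
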