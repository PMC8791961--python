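import numpy as np
import pandas as pd
import pytest

from cortmorph import synthio


@pytest.fixture(scope="session")
def atlas68():
    """68-region symmetric atlas (covariance-analysis scale)."""
    return synthio.generate_atlas(34, seed=1)


@pytest.fixture(scope="session")
def atlas148():
    """148-region symmetric atlas (group-analysis scale)."""
    return synthio.generate_atlas(74, seed=1)


@pytest.fixture(scope="session")
def default_cohort(atlas148):
    """The 3-site, 200-subject study-condition cohort with planted
    site effects, covariate effects and 20-region thinning."""
    truth = synthio.default_truth(atlas148, seed=3)
    table, meta = synthio.generate_cohort(
        atlas148, truth, synthio.DEFAULT_COHORT_PLAN, seed=5
    )
    return truth, table, meta


@pytest.fixture(scope="session")
def single_site_cohort(atlas148):
    """One site, no scanner effects: 400/group for screening tests."""
    truth = synthio.default_truth(
        atlas148, sites=("siteA",), site_shift_sd=0.0, site_scale_sd=1e-9,
        seed=3,
    )
    table, meta = synthio.generate_cohort(atlas148, truth, 400, seed=11)
    return truth, table, meta


def two_group_meta(n_per_group, seed=0):
    """Minimal metadata frame with one site and both groups."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:04d}" for i in range(n)],
            "site": "siteA",
            "group": ["VH"] * n_per_group + ["noVH"] * n_per_group,
            "age": rng.normal(66, 8.5, n),
            "gender": rng.choice(["F", "M"], n),
            "tiv": rng.normal(1.45e6, 1.5e5, n),
        }
    )
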