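import numpy as np
import pytest

from eyestrat import (
    CORRECT,
    INCORRECT,
    TIMEOUT,
    RawResponseTable,
    binarize,
    make_profile_bank,
    simulate_cohort,
)


def make_table(codes, item_ids=None, group="ASC", cohort="discovery"):
    """Build a RawResponseTable from a list of per-subject code lists."""
    codes = np.array(codes, dtype=object)
    n, m = codes.shape
    if item_ids is None:
        item_ids = tuple(f"item{j + 1:02d}" for j in range(m))
    return RawResponseTable(
        subject_ids=tuple(f"s{i + 1}" for i in range(n)),
        group=(group,) * n,
        cohort=(cohort,) * n,
        item_ids=tuple(item_ids),
        responses=codes,
    )


def random_table(rng, n_subjects=6, n_items=5, timeout_rate=0.1):
    pool = np.array([CORRECT, INCORRECT, TIMEOUT], dtype=object)
    probs = [(1 - timeout_rate) / 2, (1 - timeout_rate) / 2, timeout_rate]
    codes = rng.choice(pool, size=(n_subjects, n_items), p=probs)
    return make_table(codes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def asc_bank():
    return make_profile_bank("asc_like", seed=0)


@pytest.fixture(scope="session")
def td_bank():
    return make_profile_bank("td_like", seed=0)


@pytest.fixture(scope="session")
def asc_cohort(asc_bank):
    """One simulated ASC-like cohort (n=400) with its planted labels."""
    table, planted = simulate_cohort(asc_bank.with_seed(7))
    return binarize(table), planted
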