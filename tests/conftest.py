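import numpy as np
import pandas as pd
import pytest

from dbswin import synth
from dbswin.cli import cohort_features_targets


@pytest.fixture(scope="session")
def small_cohort():
    """Four-patient cohort, short recordings; shared across tests."""
    cfg = synth.SimConfig(n_patients=4, duration=12.0, seed=7)
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    X, y = cohort_features_targets(small_cohort)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_regression(rng):
    """Tabular toy data: 8 electrodes x 5 contacts, y driven by one feature."""
    n_elec, n_contacts = 8, 5
    idx = pd.MultiIndex.from_tuples(
        [
            (f"P{e:02d}", "right", c + 1)
            for e in range(n_elec)
            for c in range(n_contacts)
        ],
        names=["patient_id", "side", "contact_id"],
    )
    X = pd.DataFrame(
        rng.standard_normal((len(idx), 6)),
        columns=[f"f{i}" for i in range(6)],
        index=idx,
    )
    y = pd.Series(2.0 * X["f0"].to_numpy(), index=idx, name="y")
    return X, y
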