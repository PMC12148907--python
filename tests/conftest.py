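import numpy as np
import pandas as pd
import pytest

from attenurank import CohortConfig, compute_labels, generate_cohort
from attenurank.cohort import INPUT_COLUMNS
from attenurank.ranking import labels_wide

# Study conditions with a strong planted attenuation signal: high
# fitness/attenuation coupling, doubled standardized effect, low noise.
STRONG_SIGNAL = dict(correlation_strength=0.9, attenuation_effect=2.0, noise_sd=0.3)


@pytest.fixture(scope="session")
def cohort41():
    """A 41-athlete cohort under the default study conditions."""
    return generate_cohort(CohortConfig(n_athletes=41, seed=1))


@pytest.fixture(scope="session")
def labels41(cohort41):
    labels, ledger = compute_labels(cohort41)
    return labels, ledger


def features_and_targets(seed: int, n: int = 41, **conditions):
    """Model-input feature matrix and wide 0/1 target frame for one cohort."""
    table = generate_cohort(CohortConfig(n_athletes=n, seed=seed, **conditions))
    labels, _ = compute_labels(table)
    wide = labels_wide(labels).drop(columns=["athlete_id"])
    wide.columns = [c.removeprefix("group_") for c in wide.columns]
    features = table[list(INPUT_COLUMNS)].reset_index(drop=True)
    return features, wide


@pytest.fixture(scope="session")
def small_features_targets():
    return features_and_targets(seed=1, **STRONG_SIGNAL)
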