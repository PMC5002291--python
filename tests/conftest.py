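"""Shared fixtures: one synthetic cohort and one trained map per session."""

import numpy as np
import pytest

from wearmap import (SOMClusterer, default_cohort_spec, encode_cohort,
                     sample_cohort)
from wearmap.pipeline import preprocess


@pytest.fixture(scope="session")
def cohort():
    """Default study-sized cohort (21 postmortem / 54 revision / 6 simulator)."""
    images, table = sample_cohort(default_cohort_spec(master_seed=1))
    return images, table


@pytest.fixture(scope="session")
def encoded(cohort):
    """Standardized, right-normalized, encoded design matrix (81 x 37,400)."""
    images, table = cohort
    X = encode_cohort(preprocess(images)).astype(np.float32)
    return X, table


@pytest.fixture(scope="session")
def trained(encoded):
    """SOMClusterer fitted on the postmortem subset, plus full assignments."""
    X, table = encoded
    train_mask = (table["source"] == "postmortem").to_numpy()
    clst = SOMClusterer(random_state=0).fit(X[train_mask])
    assignments = clst.predict(X)
    return clst, assignments, train_mask
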