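import numpy as np
import pytest

import il13pep as m


@pytest.fixture(scope="session")
def catalog():
    return m.load_catalog()


@pytest.fixture(scope="session")
def planted_small():
    """Small planted benchmark: 30 positives / 120 negatives, signal on H."""
    spec = m.FixtureSpec(n_pos=30, n_neg=120, seed=7)
    peptides, labels = m.planted_dataset(spec)
    return peptides, labels


@pytest.fixture(scope="session")
def planted_table(planted_small, catalog):
    peptides, labels = planted_small
    return m.encode_batch(peptides, catalog), np.asarray(labels)


@pytest.fixture(scope="session")
def tiny_model(planted_table):
    """A quick real model (GNB on the top-5 mRMR features)."""
    X, y = planted_table
    ranking = m.mrmr_select(X, y, k=5)
    spec = m.ModelSpec("GNB")
    best, _ = m.cv_grid_search(X[ranking.ranked_features], y, spec, folds=3, seed=0)
    return m.train_final(X, y, spec, best, ranking.ranked_features, seed=0)
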