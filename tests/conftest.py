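"""Shared fixtures: synthetic datasets and their feature tables.

The two factorial designs (108-sample ideal, 324-sample realistic) are
generated once per session at the default study conditions and reused by
unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import aeroprint as ap
from aeroprint.fractal import FEATURE_COLUMNS


@pytest.fixture(scope="session")
def ideal_table():
    """Feature table of the 108-sample ideal design at default conditions."""
    ds = ap.generate_dataset(ap.ideal_design(), seed=1)
    return ap.extract_feature_table(ds)


@pytest.fixture(scope="session")
def realistic_table():
    """Feature table of the 324-sample realistic design at default conditions."""
    ds = ap.generate_dataset(ap.realistic_design(), seed=1)
    return ap.extract_feature_table(ds)


@pytest.fixture(scope="session")
def ideal_features(ideal_table):
    """(X, mask) after zero-variance pruning of the ideal feature table."""
    return ap.remove_zero_variance(ideal_table[FEATURE_COLUMNS].to_numpy())


@pytest.fixture(scope="session")
def realistic_features(realistic_table):
    return ap.remove_zero_variance(realistic_table[FEATURE_COLUMNS].to_numpy())


@pytest.fixture(scope="session")
def blobs4():
    """Four well-separated Gaussian blobs in 2-D (n = 120), trivially separable."""
    rng = np.random.default_rng(42)
    centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
    X = np.vstack([c + 0.4 * rng.standard_normal((30, 2)) for c in centers])
    y = np.repeat(np.arange(4), 30)
    return X, y
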