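"""Shared fixtures: desk-scale synthetic corpora and trained models.

The corpora and hyperparameters come from :mod:`rbcsmear.desk` (the fixed
desk-scale study conditions).  Training the two models takes a few minutes
each, so they are session-scoped and every test shares one fit.
"""

import warnings
from dataclasses import replace

import pytest

from rbcsmear.desk import (
    DESK_SPEC,
    REGRESSION_LEVEL_FRACTIONS,
    REGRESSION_QUOTAS,
    REGRESSION_SCANS_PER_CLASS,
    REGRESSION_TRAIN,
    STORAGE_QUOTAS,
    STORAGE_SCANS_PER_CLASS,
    STORAGE_TRAIN,
    STORAGE_WEEK_FRACTIONS,
    build_corpus_dataset,
)
from rbcsmear.nn import build_model
from rbcsmear.train_eval import train


@pytest.fixture(scope="session")
def storage_corpus():
    """Classification corpus: weeks 0/1/2 at echinocyte 0.05/0.35/0.70."""
    return build_corpus_dataset(
        STORAGE_WEEK_FRACTIONS, n_scans_per_class=STORAGE_SCANS_PER_CLASS,
        seed=42, **STORAGE_QUOTAS
    )


@pytest.fixture(scope="session")
def storage_classifier(storage_corpus):
    dataset, _ = storage_corpus
    x, y = dataset.split_arrays("train")
    model = build_model(DESK_SPEC, "storage-3", seed=1)
    train(model, dataset.normalize(x), y, replace(STORAGE_TRAIN, seed=3))
    return model


@pytest.fixture(scope="session")
def regression_corpus():
    """Regression corpus: five echinocyte levels spanning the RS range."""
    return build_corpus_dataset(
        REGRESSION_LEVEL_FRACTIONS, n_scans_per_class=REGRESSION_SCANS_PER_CLASS,
        seed=43, **REGRESSION_QUOTAS
    )


@pytest.fixture(scope="session")
def rs_regressor(regression_corpus):
    dataset, _ = regression_corpus
    x, y = dataset.regression_arrays("train")
    model = build_model(DESK_SPEC, "regression", seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train(model, dataset.normalize(x), y, replace(REGRESSION_TRAIN, seed=4))
    return model
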